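"""Structures, topologies and atom selections.

The in-memory model mirrors what a molecular-mechanics calculation needs:

* :class:`Topology` — ordered atoms with force-field parameters (partial
  charges, 12-6 Lennard-Jones Rmin/2 and epsilon, intrinsic generalized-Born
  radii and screening factors) plus bonded terms (bonds, angles, torsions)
  and the exclusion / 1-4 lists derived from the bond graph.
* :class:`ConformationEnsemble` — an ordered stack of coordinate frames
  (Angstrom) sharing one topology; one frame per trajectory snapshot or
  per MODEL block of a multi-model PDB file.
* :class:`AtomSelection` — an ordered, duplicate-free list of atom indices
  produced by a small selection grammar (``resid 207-219 and main-chain``).

Residue numbers are kept verbatim from the input (author numbering); atom
indices are 0-based internally.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    EnsembleError,
    PDBParseError,
    SelectionError,
    TopologyError,
)

MAIN_CHAIN_NAMES = ("N", "CA", "C", "O")
WATER_RESNAMES = ("HOH", "WAT", "TIP3")
ION_RESNAMES = ("NA", "CL", "K", "MG", "NA+", "CL-")


@dataclass
class Atom:
    name: str
    element: str
    resname: str
    resid: int
    chain: str = "A"
    icode: str = ""
    charge: float | None = None          # elementary charges
    rmin_half: float | None = None       # LJ Rmin/2, Angstrom
    epsilon: float | None = None         # LJ well depth, kcal/mol
    gb_radius: float | None = None       # intrinsic Born radius, Angstrom
    gb_screen: float | None = None       # HCT screening factor

    @property
    def is_water(self) -> bool:
        return self.resname.upper() in WATER_RESNAMES

    @property
    def is_ion(self) -> bool:
        return self.resname.upper() in ION_RESNAMES or (
            self.element.upper() == "ZN" or self.resname.upper() == "ZN"
        )


@dataclass
class BondTerm:
    i: int
    j: int
    k: float | None = None      # kcal/mol/A^2
    b0: float | None = None     # A


@dataclass
class AngleTerm:
    i: int
    j: int
    k: int
    force: float | None = None  # kcal/mol/rad^2
    theta0: float | None = None  # degrees


@dataclass
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    barrier: float | None = None     # V_n, kcal/mol
    periodicity: int | None = None   # n
    phase: float | None = None       # gamma, degrees


@dataclass
class Topology:
    """Ordered atoms plus force-field terms.

    ``energy_offset`` is a constant (kcal/mol) added to the molecular-
    mechanics energy of every snapshot evaluated with this topology; the
    synthetic two-state generator uses it to set enthalpy differences
    exactly.
    """

    atoms: list[Atom]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    torsions: list[TorsionTerm] = field(default_factory=list)
    energy_offset: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if b.i == b.j or not (0 <= b.i < n and 0 <= b.j < n):
                raise TopologyError(
                    f"bond ({b.i}, {b.j}) does not reference two distinct "
                    f"valid atom indices (n_atoms={n})"
                )
        self._exclusions: set[tuple[int, int]] | None = None
        self._pairs14: set[tuple[int, int]] | None = None

    # -- basic views -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def charges(self) -> np.ndarray:
        return np.array(
            [a.charge if a.charge is not None else np.nan for a in self.atoms]
        )

    def gb_radii(self) -> np.ndarray:
        return np.array(
            [a.gb_radius if a.gb_radius is not None else np.nan
             for a in self.atoms]
        )

    def gb_screens(self) -> np.ndarray:
        return np.array(
            [a.gb_screen if a.gb_screen is not None else np.nan
             for a in self.atoms]
        )

    def vdw_radii(self) -> np.ndarray:
        return np.array(
            [a.rmin_half if a.rmin_half is not None else np.nan
             for a in self.atoms]
        )

    def bonded_neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return [sorted(x) for x in adj]

    def require_parameters(self) -> None:
        """Raise TopologyError naming the first missing parameter."""
        for idx, a in enumerate(self.atoms):
            for attr in ("charge", "rmin_half", "epsilon",
                         "gb_radius", "gb_screen"):
                if getattr(a, attr) is None:
                    raise TopologyError(
                        f"atom {idx} ({a.name} {a.resname}{a.resid}) "
                        f"lacks parameter '{attr}'"
                    )
        for r in self.gb_radii():
            if not r > 0:
                raise TopologyError("all GB radii must be > 0")

    # -- exclusion machinery ----------------------------------------------
    def _build_exclusions(self) -> None:
        adj = self.bonded_neighbors()
        excl: set[tuple[int, int]] = set()
        pairs14: set[tuple[int, int]] = set()
        for i in range(self.n_atoms):
            for j in adj[i]:                      # 1-2
                if i < j:
                    excl.add((i, j))
                for k in adj[j]:                  # 1-3
                    if k != i and i < k:
                        excl.add((i, k))
                    for l in adj[k]:              # 1-4
                        if l not in (i, j) and i < l:
                            pairs14.add((i, l))
        pairs14 -= excl
        self._exclusions = excl
        self._pairs14 = pairs14

    def exclusions(self) -> set[tuple[int, int]]:
        """1-2 and 1-3 pairs (i < j)."""
        if self._exclusions is None:
            self._build_exclusions()
        return self._exclusions  # type: ignore[return-value]

    def pairs14(self) -> set[tuple[int, int]]:
        """1-4 pairs (i < j), excluding any that are also 1-2/1-3."""
        if self._pairs14 is None:
            self._build_exclusions()
        return self._pairs14  # type: ignore[return-value]

    def subset(self, indices: "AtomSelection | np.ndarray") -> "Topology":
        """New topology over ``indices``; bonded terms fully inside survive."""
        idx = np.asarray(getattr(indices, "indices", indices), dtype=int)
        keep = {int(old): new for new, old in enumerate(idx)}
        atoms = [replace(self.atoms[i]) for i in idx]
        bonds = [BondTerm(keep[b.i], keep[b.j], b.k, b.b0)
                 for b in self.bonds if b.i in keep and b.j in keep]
        angles = [AngleTerm(keep[a.i], keep[a.j], keep[a.k], a.force, a.theta0)
                  for a in self.angles
                  if a.i in keep and a.j in keep and a.k in keep]
        torsions = [TorsionTerm(keep[t.i], keep[t.j], keep[t.k], keep[t.l],
                                t.barrier, t.periodicity, t.phase)
                    for t in self.torsions
                    if all(x in keep for x in (t.i, t.j, t.k, t.l))]
        return Topology(atoms, bonds, angles, torsions, self.energy_offset)


@dataclass
class AtomSelection:
    """Ordered, unique atom indices with a human-readable label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise SelectionError(f"duplicate indices in selection {self.label!r}")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


class ConformationEnsemble:
    """Coordinate frames (frames, atoms, 3) in Angstrom over one topology."""

    def __init__(self, topology: Topology, coordinates: np.ndarray,
                 metadata: list[dict] | None = None):
        coords = np.asarray(coordinates, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise EnsembleError(
                f"coordinates must have shape (frames, atoms, 3); "
                f"got {coords.shape}"
            )
        if coords.shape[0] == 0:
            raise EnsembleError("ensemble must contain at least one frame")
        if coords.shape[1] != topology.n_atoms:
            raise EnsembleError(
                f"frame has {coords.shape[1]} atoms but topology has "
                f"{topology.n_atoms}"
            )
        if np.isnan(coords).any():
            raise EnsembleError("NaN coordinates are not allowed")
        self.topology = topology
        self.coordinates = coords
        self.metadata = metadata if metadata is not None else [
            {} for _ in range(coords.shape[0])
        ]

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def with_coordinates(self, coords: np.ndarray) -> "ConformationEnsemble":
        return ConformationEnsemble(self.topology, coords,
                                    [dict(m) for m in self.metadata])

    def subset_atoms(self, selection: AtomSelection) -> "ConformationEnsemble":
        topo = self.topology.subset(selection)
        return ConformationEnsemble(
            topo, self.coordinates[:, selection.indices, :],
            [dict(m) for m in self.metadata])


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_ELEMENT_FROM_NAME = re.compile(r"([A-Za-z])")


def _infer_element(name: str, resname: str) -> str:
    stripped = name.strip()
    if resname.strip().upper() == "ZN" or stripped.upper() in ("ZN", "ZN2"):
        return "Zn"
    m = _ELEMENT_FROM_NAME.search(stripped)
    if not m:
        return "X"
    first = m.group(1).upper()
    # two-letter elements that appear in this domain
    two = stripped[:2].upper()
    if two in ("ZN", "CL", "NA", "MG", "FE", "BR"):
        return two.capitalize()
    return first


def read_structure(path, fmt: str = "pdb") -> ConformationEnsemble:
    """Read a (multi-model) PDB file into an ensemble.

    One frame per MODEL block; a file without MODEL records yields a single
    frame.  A minimal topology (names, residues, elements) is built; force
    field parameters remain unset until :func:`assign_parameters` or a
    parameterized topology is supplied.  For atoms with alternate locations
    only the highest-occupancy conformer is kept.
    """
    if fmt != "pdb":
        raise ValueError(f"unsupported structure format {fmt!r}")
    frames: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model and current:
                    frames.append(current)
                    current = []
                in_model = True
                saw_model = True
            elif rec == "ENDMDL":
                frames.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    name = line[12:16].strip()
                    altloc = line[16].strip()
                    resname = line[17:20].strip()
                    chain = line[21].strip() or "A"
                    resid = int(line[22:26])
                    icode = line[26].strip()
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    occ_str = line[54:60].strip()
                    occupancy = float(occ_str) if occ_str else 1.0
                    element = line[76:78].strip() if len(line) >= 78 else ""
                except (ValueError, IndexError) as exc:
                    raise PDBParseError(
                        f"malformed ATOM/HETATM record: {exc}", lineno
                    ) from None
                if not element:
                    element = _infer_element(name, resname)
                current.append((name, altloc, resname, chain, resid, icode,
                                x, y, z, occupancy, element))
    if current:
        frames.append(current)
    frames = [f for f in frames if f]
    if not frames:
        raise PDBParseError("no atoms found in file")

    frames = [_resolve_altloc(f) for f in frames]
    n0 = len(frames[0])
    for k, f in enumerate(frames):
        if len(f) != n0:
            raise EnsembleError(
                f"MODEL {k + 1} has {len(f)} atoms but MODEL 1 has {n0}"
            )
    atoms = [
        Atom(name=a[0], element=a[10], resname=a[2], resid=a[4],
             chain=a[3], icode=a[5])
        for a in frames[0]
    ]
    coords = np.array(
        [[(a[6], a[7], a[8]) for a in f] for f in frames], dtype=float
    )
    topo = Topology(atoms)
    meta = [{"model": i + 1, "multi_model": saw_model}
            for i in range(len(frames))]
    return ConformationEnsemble(topo, coords, meta)


def _resolve_altloc(atoms: list[tuple]) -> list[tuple]:
    """Keep only the highest-occupancy alternate-location conformer."""
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a[0], a[2], a[3], a[4], a[5])  # name, resname, chain, resid, icode
        if key not in best:
            best[key] = a
            order.append(key)
        elif a[9] > best[key][9]:
            best[key] = a
    return [best[k] for k in order]


def write_ensemble(ensemble: ConformationEnsemble, path) -> None:
    """Write a multi-model PDB (one MODEL block per frame when > 1 frame)."""
    if ensemble.n_frames == 0:
        raise EnsembleError("cannot write an empty ensemble")
    multi = ensemble.n_frames > 1
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            for i, atom in enumerate(ensemble.topology.atoms):
                x, y, z = ensemble.coordinates[f, i]
                name = atom.name
                if len(name) < 4:
                    name = f" {name:<3s}"
                record = "HETATM" if atom.is_water or atom.is_ion else "ATOM  "
                fh.write(
                    f"{record}{i + 1:5d} {name:<4s}{'':1s}{atom.resname:<3s} "
                    f"{atom.chain:1s}{atom.resid:4d}{atom.icode:<1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Toy topology file format (YAML)
# ---------------------------------------------------------------------------

_ATOM_FIELDS = ("name", "element", "resname", "resid", "chain",
                "charge", "rmin_half", "epsilon", "gb_radius", "gb_screen")


def write_topology(topology: Topology, path) -> None:
    """Serialize a fully parameterized topology to the internal YAML format."""
    import yaml

    doc = {
        "atoms": [
            {f: getattr(a, f) for f in _ATOM_FIELDS}
            for a in topology.atoms
        ],
        "bonds": [[b.i, b.j, b.k, b.b0] for b in topology.bonds],
        "angles": [[a.i, a.j, a.k, a.force, a.theta0]
                   for a in topology.angles],
        "torsions": [[t.i, t.j, t.k, t.l, t.barrier, t.periodicity, t.phase]
                     for t in topology.torsions],
        "energy_offset": float(topology.energy_offset),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_topology(path, fmt: str = "internal-toy") -> Topology:
    """Read a fully parameterized topology.

    The internal toy format is YAML with ``atoms``, ``bonds``, ``angles``
    and ``torsions`` sections; every atom must carry charge, LJ, and GB
    parameters.  A missing section or parameter raises TopologyError naming
    it.
    """
    import yaml

    if fmt not in ("internal-toy", "prmtop-like"):
        raise ValueError(f"unsupported topology format {fmt!r}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for section in ("atoms", "bonds"):
        if section not in doc:
            raise TopologyError(f"topology file missing section {section!r}")
    atoms = []
    for k, rec in enumerate(doc["atoms"]):
        missing = [f for f in _ATOM_FIELDS if f not in rec or rec[f] is None]
        # chain/icode may legitimately default
        missing = [m for m in missing if m not in ("chain",)]
        if missing:
            raise TopologyError(
                f"atom {k} missing parameter(s): {', '.join(missing)}"
            )
        atoms.append(Atom(
            name=str(rec["name"]), element=str(rec["element"]),
            resname=str(rec["resname"]), resid=int(rec["resid"]),
            chain=str(rec.get("chain", "A")),
            charge=float(rec["charge"]),
            rmin_half=float(rec["rmin_half"]),
            epsilon=float(rec["epsilon"]),
            gb_radius=float(rec["gb_radius"]),
            gb_screen=float(rec["gb_screen"]),
        ))
    bonds = [BondTerm(int(i), int(j),
                      float(k) if k is not None else None,
                      float(b0) if b0 is not None else None)
             for i, j, k, b0 in doc["bonds"]]
    angles = [AngleTerm(int(i), int(j), int(k),
                        float(f) if f is not None else None,
                        float(t0) if t0 is not None else None)
              for i, j, k, f, t0 in doc.get("angles", [])]
    torsions = [TorsionTerm(int(i), int(j), int(k), int(l),
                            float(v) if v is not None else None,
                            int(n) if n is not None else None,
                            float(g) if g is not None else None)
                for i, j, k, l, v, n, g in doc.get("torsions", [])]
    topo = Topology(atoms, bonds, angles, torsions,
                    float(doc.get("energy_offset", 0.0)))
    topo.require_parameters()
    return topo


def assign_parameters(topology: Topology, parameterized: Topology) -> Topology:
    """Copy force-field parameters onto a structure-derived topology.

    Atoms are matched by order; atom counts must agree.
    """
    if topology.n_atoms != parameterized.n_atoms:
        raise TopologyError(
            f"atom count mismatch: structure has {topology.n_atoms}, "
            f"parameter topology has {parameterized.n_atoms}"
        )
    atoms = []
    for a, p in zip(topology.atoms, parameterized.atoms):
        atoms.append(replace(
            a, charge=p.charge, rmin_half=p.rmin_half, epsilon=p.epsilon,
            gb_radius=p.gb_radius, gb_screen=p.gb_screen))
    return Topology(atoms, list(parameterized.bonds),
                    list(parameterized.angles), list(parameterized.torsions),
                    parameterized.energy_offset)


def strip_solvent(ensemble: ConformationEnsemble,
                  remove_ions: bool = True) -> tuple[ConformationEnsemble, int]:
    """Remove water (and by default counter-ion) atoms; returns the count.

    Explicit and logged rather than silent: callers are expected to report
    the returned count.  The catalytic metal (Zn) is kept.
    """
    keep = []
    removed = 0
    for i, a in enumerate(ensemble.topology.atoms):
        drop = a.is_water or (
            remove_ions
            and a.resname.upper() in ION_RESNAMES
            and a.element.upper() != "ZN"
        )
        if drop:
            removed += 1
        else:
            keep.append(i)
    sel = AtomSelection(np.array(keep, dtype=int), "non-solvent")
    return ensemble.subset_atoms(sel), removed


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[A-Za-z0-9_\-\+\*\.\{\},=]+))"
)


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m or m.end() == pos:
            raise SelectionError("unexpected character", pos)
        if m.group("lpar"):
            tokens.append(("(", m.start("lpar")))
        elif m.group("rpar"):
            tokens.append((")", m.start("rpar")))
        else:
            tokens.append((m.group("word"), m.start("word")))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser producing a per-atom boolean mask."""

    def __init__(self, tokens: list[tuple[str, int]], topology: Topology):
        self.tokens = tokens
        self.topology = topology
        self.k = 0

    def peek(self):
        return self.tokens[self.k] if self.k < len(self.tokens) else (None, -1)

    def next(self):
        tok = self.peek()
        self.k += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        tok, pos = self.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r}", pos)
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek()[0] == "or":
            self.next()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek()[0] == "and":
            self.next()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        if self.peek()[0] == "not":
            self.next()
            return ~self.parse_not()
        return self.parse_primary()

    def parse_primary(self) -> np.ndarray:
        tok, pos = self.next()
        if tok is None:
            raise SelectionError("unexpected end of expression", pos)
        if tok == "(":
            mask = self.parse_or()
            tok2, pos2 = self.next()
            if tok2 != ")":
                raise SelectionError("expected ')'", pos2)
            return mask
        return self._term(tok, pos)

    # -- terms -------------------------------------------------------------
    def _atoms_attr(self, fn) -> np.ndarray:
        return np.array([fn(a) for a in self.topology.atoms], dtype=bool)

    def _term(self, tok: str, pos: int) -> np.ndarray:
        low = tok.lower()
        if "=" in tok:
            key, _, val = tok.partition("=")
            return self._keyval(key.lower(), val, pos)
        if low in ("main-chain", "mainchain", "backbone"):
            return self._atoms_attr(
                lambda a: a.name.upper() in MAIN_CHAIN_NAMES)
        if low == "water":
            return self._atoms_attr(lambda a: a.is_water)
        if low == "all":
            return np.ones(self.topology.n_atoms, dtype=bool)
        if low in ("resid", "resname", "name", "element", "chain"):
            val_tok, vpos = self.next()
            if val_tok is None or val_tok in ("(", ")", "and", "or", "not"):
                raise SelectionError(f"{low} requires a value", vpos)
            if low == "name" and val_tok == "in":
                set_tok, spos = self.next()
                if set_tok is None:
                    raise SelectionError("expected {...} after 'name in'", spos)
                return self._keyval("name", set_tok, spos)
            return self._keyval(low, val_tok, vpos)
        raise SelectionError(f"unknown selection term {tok!r}", pos)

    def _keyval(self, key: str, val: str, pos: int) -> np.ndarray:
        if key == "resid":
            if "-" in val.strip("-"):
                lo_s, _, hi_s = val.partition("-")
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError:
                    raise SelectionError(f"bad residue range {val!r}", pos)
            else:
                try:
                    lo = hi = int(val)
                except ValueError:
                    raise SelectionError(f"bad residue id {val!r}", pos)
            return self._atoms_attr(lambda a: lo <= a.resid <= hi)
        values = {v.strip().upper()
                  for v in val.strip("{}").split(",") if v.strip()}
        if not values:
            raise SelectionError(f"empty value for {key!r}", pos)
        if key == "name":
            return self._atoms_attr(lambda a: a.name.upper() in values)
        if key == "resname":
            return self._atoms_attr(lambda a: a.resname.upper() in values)
        if key == "element":
            return self._atoms_attr(lambda a: a.element.upper() in values)
        if key == "chain":
            return self._atoms_attr(lambda a: a.chain.upper() in values)
        raise SelectionError(f"unknown selection key {key!r}", pos)


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression on a topology.

    Grammar: ``element=X``, ``name=X`` / ``name in {N,CA,...}``,
    ``resname=X`` / ``resname X``, ``resid A-B``, the macros ``main-chain``,
    ``water``, ``all``, combined with ``and`` / ``or`` / ``not`` and
    parentheses.  The result preserves atom order.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression", 0)
    mask = _Parser(tokens, topology).parse()
    return AtomSelection(np.nonzero(mask)[0], expression)


def config_hash(obj) -> str:
    """Short deterministic hash of a (nested) plain-python config object."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]
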