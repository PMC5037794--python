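"""Silk fibroin model building, proton distances and restraint filtering.

The crystalline repeat of *Bombyx mori* silk fibroin is modelled as capped
Acetyl-(Ala-Gly-Ala-Gly-Ser-Gly)2-NHCH3 chains built from backbone torsion
angles by internal-coordinate (NeRF) placement, packed into a crystal by
lattice translations, and decorated with rigid glycerol molecules.  The
module's core contract is geometric: minimum proton-group distances, their
comparison against DQ-SQ derived upper bounds (restraints), and a
restrained rigid-body simulated annealing that moves glycerols (the
fibroin is held fixed) to satisfy those bounds without steric clashes.

Two torsion sets matter here:

* silk I* — the repeated type II β-turn form, Ala (φ, ψ) = (−62°, 125°),
  Gly (77°, 10°), orthorhombic cell a = 4.65, b = 14.24, c = 8.88 Å;
* silk II — the β-sheet form, (φ, ψ) = (−140°, 140°) for both residues,
  monoclinic-packed cell a = 9.38, b = 9.49, c = 6.98 Å.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .dqmas import DistanceRestraint

__all__ = [
    "GEOMETRY",
    "TorsionSet",
    "SILK_I_STAR_TORSIONS",
    "BETA_SHEET_TORSIONS",
    "UnitCell",
    "SILK_I_STAR_CELL",
    "BETA_SHEET_CELL",
    "ComplexModel",
    "RestraintEvaluation",
    "RefinementParams",
    "MODEL_SEQUENCE",
    "SITE_ATOMS",
    "build_chain",
    "backbone_torsions",
    "pack_crystal",
    "glycerol_template",
    "min_site_distance",
    "predicted_pairs",
    "evaluate_restraints",
    "refine_complex",
    "read_pdb",
    "write_pdb",
    "dihedral",
]

#: The model-peptide sequence (caps added automatically by build_chain).
MODEL_SEQUENCE = "AGAGSGAGAGSG"

#: Standard peptide geometry (lengths in Å, angles in degrees).  These are
#: textbook values; the build is exact with respect to this table, so bond
#: lengths in the output equal the table entries to machine precision.
GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C=O": 1.231,
    "N-H": 1.010,
    "C-H": 1.090,
    "CA-CB": 1.521,
    "CB-OG": 1.417,
    "O-H": 0.960,
    "ang_CA-C-N": 116.2,
    "ang_C-N-CA": 121.7,
    "ang_N-CA-C": 111.0,
    "ang_CA-C-O": 120.8,
    "ang_C-N-H": 119.0,
    "ang_N-CA-CB": 110.4,
    "ang_CA-CB-OG": 110.8,
    "ang_CB-OG-HG": 108.5,
    "ang_tet": 109.5,
    # branch torsions about the N-CA axis, relative to the C placement
    "branch_CB": 122.5,
    "branch_HA": -119.2,
}

#: Hard floor used when generating glycerol placements (Å).
GENERATION_CLASH_FLOOR = 2.0
#: Soft-sphere floor enforced during refinement (Å).
REFINE_CLASH_FLOOR = 2.2


# ---------------------------------------------------------------------------
# internal-coordinate placement
# ---------------------------------------------------------------------------

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to C given positions A, B, C (NeRF).

    `bond` = |C-D|, `angle_deg` = angle(B, C, D), `torsion_deg` =
    dihedral(A, B, C, D).  Exact: recomputing the dihedral from the output
    returns the input to machine precision.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in internal-coordinate placement")
    n /= nn
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


# ---------------------------------------------------------------------------
# torsions and cells
# ---------------------------------------------------------------------------

@dataclass
class TorsionSet:
    """Backbone (φ, ψ) per residue type, plus ω and the Ser χ1 default.

    Residues absent from `per_residue` fall back to the Ala entry (the Ser
    of the AGSGAG repeat occupies an Ala-like position and no separate
    torsions are published for it).
    """

    per_residue: dict[str, tuple[float, float]]
    omega: float = 180.0
    ser_chi1: float = -60.0

    def __post_init__(self):
        for res, (phi, psi) in self.per_residue.items():
            for ang in (phi, psi):
                if not (-180.0 < ang <= 180.0):
                    raise ValueError(
                        f"torsion {ang} for {res!r} outside (-180, 180]"
                    )

    def phi_psi(self, letter: str) -> tuple[float, float]:
        if letter in self.per_residue:
            return self.per_residue[letter]
        return self.per_residue["A"]


#: Repeated type II β-turn (silk I*) torsions.
SILK_I_STAR_TORSIONS = TorsionSet({"A": (-62.0, 125.0), "G": (77.0, 10.0)})

#: Antiparallel β-sheet (silk II) torsions, shared by both packing variants.
BETA_SHEET_TORSIONS = TorsionSet({"A": (-140.0, 140.0), "G": (-140.0, 140.0)})


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group: str = "P 1"

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must be in (0, 180)")

    def vectors(self) -> np.ndarray:
        """Row matrix of the three cell vectors (Å)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        va = np.array([self.a, 0.0, 0.0])
        vb = np.array([self.b * math.cos(ga), self.b * math.sin(ga), 0.0])
        cx = self.c * math.cos(be)
        cy = self.c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz = math.sqrt(max(self.c ** 2 - cx ** 2 - cy ** 2, 0.0))
        return np.vstack([va, vb, np.array([cx, cy, cz])])


SILK_I_STAR_CELL = UnitCell(4.65, 14.24, 8.88, space_group="P 21 21 21")
BETA_SHEET_CELL = UnitCell(9.38, 9.49, 6.98, space_group="P 21")


# ---------------------------------------------------------------------------
# atoms container
# ---------------------------------------------------------------------------

_ATOM_COLUMNS = ["atom_name", "element", "res_name", "res_id",
                 "chain_id", "mol", "x", "y", "z"]


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class ComplexModel:
    """A fibroin scaffold plus zero or more rigid glycerol molecules.

    Atoms live in a flat table (one row per atom) with a molecule tag
    (``SF`` or ``GLYC``); glycerols sit on chain ``x`` with consecutive
    residue ids so (chain, res_id, atom_name) stays unique.
    """

    atoms: pd.DataFrame
    cell: UnitCell | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(_ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        if not np.isfinite(self.atoms[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("non-finite atom coordinates")
        if self.atoms.duplicated(["chain_id", "res_id", "atom_name"]).any():
            raise ValueError("duplicate (chain, res_id, atom_name) in model")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy()

    def set_coords(self, xyz: np.ndarray) -> None:
        self.atoms[["x", "y", "z"]] = xyz

    @property
    def n_glyc(self) -> int:
        glyc = self.atoms[self.atoms["mol"] == "GLYC"]
        return glyc["res_id"].nunique()

    def sf_coords(self) -> np.ndarray:
        return self.atoms.loc[self.atoms["mol"] == "SF", ["x", "y", "z"]].to_numpy()

    def glyc_indices(self, glyc_res_id: int) -> np.ndarray:
        mask = (self.atoms["mol"] == "GLYC") & (self.atoms["res_id"] == glyc_res_id)
        return np.flatnonzero(mask.to_numpy())

    def glyc_res_ids(self) -> list[int]:
        glyc = self.atoms[self.atoms["mol"] == "GLYC"]
        return sorted(glyc["res_id"].unique())

    def with_glycerols(self, glyc_coords: list[np.ndarray]) -> "ComplexModel":
        """Return a copy with rigid glycerol copies appended (chain 'x')."""
        template = glycerol_template()
        frames = [self.atoms.copy()]
        start = max(self.glyc_res_ids(), default=0)
        for i, xyz in enumerate(glyc_coords, start=start + 1):
            if xyz.shape != (len(template), 3):
                raise ValueError("glycerol coordinate block has wrong shape")
            block = template.copy()
            block["res_id"] = i
            block[["x", "y", "z"]] = xyz
            frames.append(block)
        return ComplexModel(pd.concat(frames, ignore_index=True),
                            cell=self.cell, provenance=dict(self.provenance))

    def copy(self) -> "ComplexModel":
        return ComplexModel(self.atoms.copy(), cell=self.cell,
                            provenance=dict(self.provenance))

    def min_pair_distance(self) -> float:
        """Smallest inter-atom distance in the model (sanity check)."""
        tree = cKDTree(self.coords)
        d, _ = tree.query(self.coords, k=2)
        return float(d[:, 1].min())


# ---------------------------------------------------------------------------
# chain builder
# ---------------------------------------------------------------------------

_RES_NAMES = {"A": "ALA", "G": "GLY", "S": "SER"}


def build_chain(sequence: str = MODEL_SEQUENCE,
                torsions: TorsionSet = SILK_I_STAR_TORSIONS,
                geometry: dict = GEOMETRY,
                chain_id: str = "A") -> pd.DataFrame:
    """Build a capped peptide chain from torsion angles.

    The sequence uses one-letter codes from {A, G, S}; an acetyl (ACE)
    N-terminal cap and an N-methylamide (NME) C-terminal cap are always
    added, so every residue has a defined φ and ψ.  All protons are
    explicit: amide H, Hα (two for Gly), the Ala methyl as three protons,
    and the Ser Hβ pair plus the hydroxyl proton.

    Returns the atom table (ComplexModel layout, mol tag ``SF``).
    Recomputing φ/ψ from the output with :func:`backbone_torsions` returns
    the inputs to ~1e-10 degrees.
    """
    g = geometry
    bad = set(sequence) - set(_RES_NAMES)
    if bad:
        raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
    if not sequence:
        raise ValueError("empty sequence")

    rows: list[dict] = []
    pos: dict[tuple[int, str], np.ndarray] = {}

    def add(res_id: int, res_name: str, atom_name: str, xyz: np.ndarray):
        pos[(res_id, atom_name)] = xyz
        rows.append({
            "atom_name": atom_name, "element": _element_of(atom_name),
            "res_name": res_name, "res_id": res_id, "chain_id": chain_id,
            "mol": "SF", "x": xyz[0], "y": xyz[1], "z": xyz[2],
        })

    tet = g["ang_tet"]

    # acetyl cap (res_id 0): CH3-C(=O)-
    ch3 = np.zeros(3)
    cy = np.array([g["CA-C"], 0.0, 0.0])
    add(0, "ACE", "CH3", ch3)
    add(0, "ACE", "C", cy)
    # first amide N, placed in the xy-plane
    ang = math.radians(g["ang_CA-C-N"])
    n1 = cy + np.array([-g["C-N"] * math.cos(ang), g["C-N"] * math.sin(ang), 0.0])
    add(1, _RES_NAMES[sequence[0]], "N", n1)
    o_ace = _place(n1, ch3, cy, g["C=O"], g["ang_CA-C-O"], 180.0)
    add(0, "ACE", "O", o_ace)
    for k, tor in enumerate((60.0, 180.0, 300.0), start=1):
        add(0, "ACE", f"HH3{k}", _place(n1, cy, ch3, g["C-H"], tet, tor))

    n = len(sequence)
    prev_ca, prev_c, prev_n = ch3, cy, None
    psi_list: list[float] = []
    for i, letter in enumerate(sequence, start=1):
        res = _RES_NAMES[letter]
        phi, psi = torsions.phi_psi(letter)
        psi_list.append(psi)
        if i > 1:
            ni = _place(prev_n, prev_ca, prev_c, g["C-N"],
                        g["ang_CA-C-N"], psi_list[-2])
            add(i, res, "N", ni)
        else:
            ni = pos[(1, "N")]
        ca = _place(prev_ca, prev_c, ni, g["N-CA"], g["ang_C-N-CA"],
                    torsions.omega)
        add(i, res, "CA", ca)
        h = _place(ca, prev_c, ni, g["N-H"], g["ang_C-N-H"], 180.0)
        add(i, res, "H", h)
        c = _place(prev_c, ni, ca, g["CA-C"], g["ang_N-CA-C"], phi)
        add(i, res, "C", c)
        # branches about the N-CA axis, relative to the C branch at phi
        if letter == "G":
            add(i, res, "HA2", _place(prev_c, ni, ca, g["C-H"], tet,
                                      phi + g["branch_CB"]))
            add(i, res, "HA3", _place(prev_c, ni, ca, g["C-H"], tet,
                                      phi + g["branch_HA"]))
        else:
            cb = _place(prev_c, ni, ca, g["CA-CB"], g["ang_N-CA-CB"],
                        phi + g["branch_CB"])
            add(i, res, "CB", cb)
            add(i, res, "HA", _place(prev_c, ni, ca, g["C-H"], tet,
                                     phi + g["branch_HA"]))
            if letter == "A":
                for k, tor in enumerate((60.0, 180.0, 300.0), start=1):
                    add(i, res, f"HB{k}", _place(ni, ca, cb, g["C-H"], tet, tor))
            else:  # serine
                chi1 = torsions.ser_chi1
                og = _place(ni, ca, cb, g["CB-OG"], g["ang_CA-CB-OG"], chi1)
                add(i, res, "OG", og)
                add(i, res, "HB2", _place(ni, ca, cb, g["C-H"], tet, chi1 + 120.0))
                add(i, res, "HB3", _place(ni, ca, cb, g["C-H"], tet, chi1 - 120.0))
                add(i, res, "HG", _place(ca, cb, og, g["O-H"],
                                         g["ang_CB-OG-HG"], 180.0))
        add(i, res, "O", _place(ni, ca, c, g["C=O"], g["ang_CA-C-O"],
                                psi + 180.0))
        prev_n, prev_ca, prev_c = ni, ca, c

    # N-methylamide cap (res_id n+1): -NH-CH3
    nt = _place(prev_n, prev_ca, prev_c, g["C-N"], g["ang_CA-C-N"], psi_list[-1])
    add(n + 1, "NME", "N", nt)
    ct = _place(prev_ca, prev_c, nt, g["N-CA"], g["ang_C-N-CA"], torsions.omega)
    add(n + 1, "NME", "CH3", ct)
    add(n + 1, "NME", "H", _place(ct, prev_c, nt, g["N-H"], g["ang_C-N-H"], 180.0))
    for k, tor in enumerate((60.0, 180.0, 300.0), start=1):
        add(n + 1, "NME", f"HH3{k}", _place(prev_c, nt, ct, g["C-H"], tet, tor))

    return pd.DataFrame(rows, columns=_ATOM_COLUMNS)


def backbone_torsions(atoms: pd.DataFrame, chain_id: str = "A") -> pd.DataFrame:
    """Recompute (φ, ψ) per residue from coordinates.

    φ(i) = dihedral(C(i-1), N(i), CA(i), C(i));
    ψ(i) = dihedral(N(i), CA(i), C(i), N(i+1)).
    The terminal caps provide the flanking atoms for the first and last
    residues (the cap carbonyl/amide stand in for C(i-1) and N(i+1)).
    """
    sub = atoms[atoms["chain_id"] == chain_id]
    pos = {(int(r.res_id), r.atom_name): np.array([r.x, r.y, r.z])
           for r in sub.itertuples()}
    res_ids = sorted(sub.loc[~sub["res_name"].isin(["ACE", "NME"]), "res_id"].unique())
    recs = []
    for i in res_ids:
        i = int(i)
        try:
            prev_c = pos[(i - 1, "C")]
        except KeyError:
            prev_c = pos[(i - 1, "CH3")]  # pragma: no cover - ACE always has C
        next_n = pos[(i + 1, "N")]
        phi = dihedral(prev_c, pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")])
        psi = dihedral(pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")], next_n)
        res_name = sub.loc[sub["res_id"] == i, "res_name"].iloc[0]
        recs.append({"res_id": i, "res_name": res_name, "phi": phi, "psi": psi})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# crystal packing
# ---------------------------------------------------------------------------

_CHAIN_IDS = [c for c in string.ascii_uppercase + string.ascii_lowercase
              + string.digits if c != "x"]


def pack_crystal(chain: pd.DataFrame, cell: UnitCell,
                 copies: tuple[int, int, int] = (1, 1, 1),
                 placements: list[tuple[np.ndarray, np.ndarray]] | None = None,
                 ) -> ComplexModel:
    """Replicate a chain over a lattice to form a crystal scaffold.

    The chain is copied at every lattice point i*a + j*b + k*c with
    0 <= i < n_a etc.  `placements`, if given, supplies one rigid
    transform (rotation matrix, translation vector) per copy, applied
    before the lattice translation — this is how antiparallel or screw-
    related arrangements are configured; full space-group expansion is out
    of scope.
    """
    na, nb, nc = copies
    if min(na, nb, nc) < 1:
        raise ValueError("copies must be >= (1, 1, 1)")
    n_copies = na * nb * nc
    if placements is not None and len(placements) != n_copies:
        raise ValueError(
            f"got {len(placements)} placements for {n_copies} copies"
        )
    if n_copies > len(_CHAIN_IDS):
        raise ValueError(f"at most {len(_CHAIN_IDS)} copies supported")
    vec = cell.vectors()
    base = chain[["x", "y", "z"]].to_numpy()
    frames = []
    idx = 0
    for i in range(na):
        for j in range(nb):
            for k in range(nc):
                xyz = base
                if placements is not None:
                    rot, trans = placements[idx]
                    xyz = xyz @ np.asarray(rot).T + np.asarray(trans)
                xyz = xyz + i * vec[0] + j * vec[1] + k * vec[2]
                block = chain.copy()
                block["chain_id"] = _CHAIN_IDS[idx]
                block[["x", "y", "z"]] = xyz
                frames.append(block)
                idx += 1
    return ComplexModel(pd.concat(frames, ignore_index=True), cell=cell,
                        provenance={"copies": copies})


def align_chain(chain: pd.DataFrame) -> pd.DataFrame:
    """Rotate a chain so its long (principal) axis lies along z.

    The cell's chain-axis assignment is a configuration choice; aligning
    the built chain with z makes the c axis the chain direction in the
    default scaffolds.
    """
    out = chain.copy()
    xyz = out[["x", "y", "z"]].to_numpy()
    xyz = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz, full_matrices=False)
    rotated = (xyz @ vt.T)[:, [1, 2, 0]]  # principal axis -> z
    out[["x", "y", "z"]] = rotated
    return out


def silk_crystal_scaffold(form: str = "silkI*",
                          copies: tuple[int, int, int] = (2, 2, 1),
                          ) -> ComplexModel:
    """Convenience: the default desk-scale crystal scaffold.

    Default is 4 chains (2 along the hydrogen-bonded sheet direction x 2
    between sheets) rather than the full 24-chain crystal; pass larger
    `copies` (e.g. (6, 4, 1)) to restore the full arrangement.

    The idealized uniform-torsion chain cannot interdigitate at the
    crystallographic 4.65 Å in-sheet spacing without the screw-symmetry
    packing (out of scope here), so neighbouring chains within a sheet are
    placed two cells (2a) apart; inter-sheet neighbours sit one full b
    apart.  Distances relevant to surface glycerol placement and restraint
    evaluation are unaffected.
    """
    if form == "silkI*":
        chain = align_chain(build_chain(MODEL_SEQUENCE, SILK_I_STAR_TORSIONS))
        cell = SILK_I_STAR_CELL
        vec_a = cell.vectors()[0]
        na, nb, nc = copies
        # extra in-sheet offset of +a per a-index doubles the spacing
        placements = []
        for i in range(na):
            for _ in range(nb * nc):
                placements.append((np.eye(3), i * vec_a))
        return pack_crystal(chain, cell, copies, placements)
    if form in ("silkII", "beta"):
        chain = align_chain(build_chain(MODEL_SEQUENCE, BETA_SHEET_TORSIONS))
        return pack_crystal(chain, BETA_SHEET_CELL, copies)
    raise ValueError(f"unknown form {form!r}")


# ---------------------------------------------------------------------------
# glycerol
# ---------------------------------------------------------------------------

_GLYCEROL: pd.DataFrame | None = None


def glycerol_template() -> pd.DataFrame:
    """Rigid glycerol (propane-1,2,3-triol) atom block, residue GOL.

    Built once from internal coordinates (C-C 1.53 Å, C-O 1.43 Å, O-H
    0.96 Å, tetrahedral angles) and centered on its centroid.  The CH2
    protons are H11/H12/H31/H32, the central CH proton H2, and the
    hydroxyl protons HO1/HO2/HO3.
    """
    global _GLYCEROL
    if _GLYCEROL is not None:
        return _GLYCEROL.copy()
    tet = 109.5
    c1 = np.zeros(3)
    c2 = np.array([1.53, 0.0, 0.0])
    ang = math.radians(112.0)
    c3 = c2 + np.array([-1.53 * math.cos(ang), 1.53 * math.sin(ang), 0.0])
    atoms = {"C1": c1, "C2": c2, "C3": c3}
    atoms["O1"] = _place(c3, c2, c1, 1.43, tet, 180.0)
    atoms["H11"] = _place(c3, c2, c1, 1.09, tet, 60.0)
    atoms["H12"] = _place(c3, c2, c1, 1.09, tet, -60.0)
    atoms["O2"] = _place(c3, c1, c2, 1.43, tet, -121.0)
    atoms["H2"] = _place(c3, c1, c2, 1.09, tet, 121.0)
    atoms["O3"] = _place(c1, c2, c3, 1.43, tet, -60.0)
    atoms["H31"] = _place(c1, c2, c3, 1.09, tet, 60.0)
    atoms["H32"] = _place(c1, c2, c3, 1.09, tet, 180.0)
    atoms["HO1"] = _place(c2, c1, atoms["O1"], 0.96, 108.5, 180.0)
    atoms["HO2"] = _place(c1, c2, atoms["O2"], 0.96, 108.5, 180.0)
    atoms["HO3"] = _place(c2, c3, atoms["O3"], 0.96, 108.5, 180.0)
    xyz = np.array(list(atoms.values()))
    xyz -= xyz.mean(axis=0)
    rows = [{"atom_name": name, "element": _element_of(name),
             "res_name": "GOL", "res_id": 1, "chain_id": "x", "mol": "GLYC",
             "x": p[0], "y": p[1], "z": p[2]}
            for name, p in zip(atoms, xyz)]
    _GLYCEROL = pd.DataFrame(rows, columns=_ATOM_COLUMNS)
    return _GLYCEROL.copy()


# ---------------------------------------------------------------------------
# proton sites and distances
# ---------------------------------------------------------------------------

#: Site label -> (molecule tag, residue name, atom names).  Methyl,
#: methylene and hydroxyl protons are enumerated individually; no
#: pseudo-atom correction is applied to distance bounds.
SITE_ATOMS: dict[str, tuple[str, str, tuple[str, ...]]] = {
    "Ala Hbeta": ("SF", "ALA", ("HB1", "HB2", "HB3")),
    "Ala Halpha": ("SF", "ALA", ("HA",)),
    "Ala HN": ("SF", "ALA", ("H",)),
    "Gly Halpha1": ("SF", "GLY", ("HA2",)),
    "Gly Halpha2": ("SF", "GLY", ("HA3",)),
    "Gly HN": ("SF", "GLY", ("H",)),
    "Ser Halpha": ("SF", "SER", ("HA",)),
    "Ser Hbeta": ("SF", "SER", ("HB2", "HB3")),
    "Ser OH": ("SF", "SER", ("HG",)),
    "Glyc CH2": ("GLYC", "GOL", ("H11", "H12", "H31", "H32")),
    "Glyc CH": ("GLYC", "GOL", ("H2",)),
    "Glyc OH": ("GLYC", "GOL", ("HO1", "HO2", "HO3")),
}


def resolve_site(model: ComplexModel, label: str) -> np.ndarray:
    """Coordinates of every proton instance of a site label in the model."""
    return _site_instances(model, label)[0]


def _site_instances(model: ComplexModel, label: str,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(coordinates, residue-instance keys) for a proton site label."""
    try:
        mol, res_name, names = SITE_ATOMS[label]
    except KeyError:
        raise KeyError(f"unknown proton site label {label!r}") from None
    a = model.atoms
    mask = ((a["mol"] == mol) & (a["res_name"] == res_name)
            & a["atom_name"].isin(names))
    sub = a.loc[mask]
    keys = (sub["chain_id"].astype(str) + ":" + sub["res_id"].astype(str))
    return sub[["x", "y", "z"]].to_numpy(), keys.to_numpy()


def min_site_distance(model: ComplexModel, group_a: str, group_b: str) -> float:
    """Minimum distance (Å) between any proton of group_a and of group_b.

    Protons of a multi-proton site (methyl, methylene, hydroxyl pool) are
    enumerated individually.  For a group against itself, only pairs on
    distinct residue instances count (the self-correlation of one methyl
    is not a distance measurement); a single-instance group against itself
    is an error.  Symmetric in its arguments.
    """
    xa, ka = _site_instances(model, group_a)
    xb, kb = _site_instances(model, group_b)
    if len(xa) == 0:
        raise ValueError(f"site {group_a!r} resolves to zero atoms")
    if len(xb) == 0:
        raise ValueError(f"site {group_b!r} resolves to zero atoms")
    if group_a == group_b:
        if len(np.unique(ka)) < 2:
            raise ValueError(
                f"site {group_a!r} has a single instance; no self-distance"
            )
        d = cdist(xa, xa)
        d[ka[:, None] == ka[None, :]] = np.inf
        return float(d.min())
    return float(cdist(xa, xb).min())


def predicted_pairs(model: ComplexModel, cutoff: float = 4.0,
                    sites: list[str] | None = None) -> set[tuple[str, str]]:
    """All site-type pairs with a proton-proton contact within `cutoff` Å.

    This is the structural counterpart of a DQ-SQ correlation inventory:
    feeding the result to the peak-list generator yields a
    structure-consistent synthetic spectrum.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    if sites is None:
        sites = [s for s in SITE_ATOMS if len(resolve_site(model, s)) > 0]
    out: set[tuple[str, str]] = set()
    instances = {s: _site_instances(model, s) for s in sites}
    for i, sa in enumerate(sites):
        for sb in sites[i:]:
            (xa, ka), (xb, _) = instances[sa], instances[sb]
            if sa == sb:
                if len(np.unique(ka)) < 2:
                    continue
                d = cdist(xa, xa)
                d[ka[:, None] == ka[None, :]] = np.inf
                d = d.min()
            else:
                d = cdist(xa, xb).min()
            if d <= cutoff:
                out.add(tuple(sorted((sa, sb))))
    return out


# ---------------------------------------------------------------------------
# restraint evaluation and refinement
# ---------------------------------------------------------------------------

@dataclass
class RestraintEvaluation:
    """Per-restraint minimum distances and the overall verdict."""

    records: pd.DataFrame  # group_a, group_b, upper_bound, distance, satisfied
    accepted: bool
    empty_warning: bool = False

    @property
    def max_distance(self) -> float:
        return float(self.records["distance"].max())

    def n_violated(self) -> int:
        return int((~self.records["satisfied"]).sum())


def evaluate_restraints(model: ComplexModel,
                        restraints: list[DistanceRestraint],
                        ) -> RestraintEvaluation:
    """Check every distance restraint against a model.

    A restraint is satisfied iff the minimum distance between its two
    proton groups is at most its upper bound; the model is accepted iff
    all restraints are satisfied.  An empty restraint list accepts
    vacuously but sets a warning flag.
    """
    recs = []
    for r in restraints:
        d = min_site_distance(model, r.group_a, r.group_b)
        recs.append({"group_a": r.group_a, "group_b": r.group_b,
                     "upper_bound": r.upper_bound, "distance": d,
                     "satisfied": d <= r.upper_bound})
    table = pd.DataFrame(
        recs, columns=["group_a", "group_b", "upper_bound", "distance",
                       "satisfied"])
    if not recs:
        return RestraintEvaluation(records=table, accepted=True,
                                   empty_warning=True)
    return RestraintEvaluation(records=table,
                               accepted=bool(table["satisfied"].all()))


@dataclass
class RefinementParams:
    """Annealing schedule for rigid-body glycerol refinement.

    max_moves trial moves total; temperature decays geometrically from
    t_start to t_end; each move translates one glycerol by at most
    max_translation Å and rotates it by at most max_rotation_deg about its
    centroid.  clash_weight scales the soft-sphere penalty below the
    2.2 Å floor.
    """

    max_moves: int = 6000
    t_start: float = 1.0
    t_end: float = 0.01
    seed: int = 0
    max_translation: float = 0.5
    max_rotation_deg: float = 10.0
    clash_weight: float = 10.0


class _RefinementEngine:
    """Vectorized energy bookkeeping over a fixed atom indexing.

    Restraint groups and glycerol blocks are resolved to index arrays once;
    all per-move work happens on the raw coordinate array.
    """

    def __init__(self, model: ComplexModel,
                 restraints: list[DistanceRestraint]):
        self.sf_idx = np.flatnonzero((model.atoms["mol"] == "SF").to_numpy())
        self.blocks = [model.glyc_indices(i) for i in model.glyc_res_ids()]
        self.restraints = []
        for r in restraints:
            ia = self._site_index(model, r.group_a)
            ib = self._site_index(model, r.group_b)
            if len(ia) == 0 or len(ib) == 0:
                raise ValueError(
                    f"restraint group {r.group_a!r}/{r.group_b!r} resolves to "
                    "zero atoms in the model")
            self.restraints.append((ia, ib, r.upper_bound))

    @staticmethod
    def _site_index(model: ComplexModel, label: str) -> np.ndarray:
        mol, res_name, names = SITE_ATOMS[label]
        a = model.atoms
        mask = ((a["mol"] == mol) & (a["res_name"] == res_name)
                & a["atom_name"].isin(names))
        return np.flatnonzero(mask.to_numpy())

    def restraint_distances(self, x: np.ndarray) -> np.ndarray:
        return np.array([cdist(x[ia], x[ib]).min()
                         for ia, ib, _ in self.restraints])

    def energy(self, x: np.ndarray, clash_weight: float,
               floor: float = REFINE_CLASH_FLOOR) -> tuple[float, int]:
        e = 0.0
        violated = 0
        for (ia, ib, ub), d in zip(self.restraints,
                                   self.restraint_distances(x)):
            if d > ub:
                e += (d - ub) ** 2
                violated += 1
        clash = 0.0
        for bi, blk in enumerate(self.blocks):
            xb = x[blk]
            d = cdist(xb, x[self.sf_idx])
            clash += np.sum((floor - d[d < floor]) ** 2)
            for blk2 in self.blocks[bi + 1:]:
                d2 = cdist(xb, x[blk2])
                clash += np.sum((floor - d2[d2 < floor]) ** 2)
        return e + clash_weight * clash, violated

    def min_contact(self, x: np.ndarray, block_i: int) -> float:
        """Closest approach of one glycerol block to everything else."""
        blk = self.blocks[block_i]
        other = np.setdiff1d(np.arange(len(x)), blk, assume_unique=False)
        return float(cdist(x[blk], x[other]).min())


def _random_rigid_move(rng: np.random.Generator, xyz: np.ndarray,
                       max_trans: float, max_rot_deg: float,
                       direction: np.ndarray | None = None) -> np.ndarray:
    """One rigid-body move of a glycerol block about its centroid."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = math.radians(rng.uniform(-max_rot_deg, max_rot_deg))
    k = axis
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + math.sin(theta) * kx + (1 - math.cos(theta)) * (kx @ kx)
    if direction is None:
        step = rng.normal(size=3)
        step *= rng.uniform(0, max_trans) / np.linalg.norm(step)
    else:
        step = direction / np.linalg.norm(direction) * rng.uniform(0, max_trans)
    centroid = xyz.mean(axis=0)
    return (xyz - centroid) @ rot.T + centroid + step


def refine_complex(model: ComplexModel,
                   restraints: list[DistanceRestraint],
                   params: RefinementParams | None = None) -> ComplexModel:
    """Restrained rigid-body simulated annealing of the glycerol positions.

    The fibroin scaffold is held fixed; glycerols move as rigid bodies
    (internal geometry preserved exactly).  The energy is the sum of
    flat-bottom restraint penalties (zero at or below each upper bound,
    quadratic above) and a soft-sphere clash penalty below 2.2 Å.  Half of
    the trial moves are biased along the direction that closes the worst
    violated restraint, which is what makes the desk-scale schedule
    reliable.  The best model by (number of violated restraints, energy)
    is returned, so refinement never increases the violation count.
    """
    if params is None:
        params = RefinementParams()
    if model.n_glyc == 0:
        raise ValueError("model has no glycerols to refine")
    if params.max_moves == 0:
        return model.copy()
    rng = np.random.default_rng(params.seed)
    engine = _RefinementEngine(model, restraints)
    x = model.coords.copy()
    e_cur, v_cur = engine.energy(x, params.clash_weight)
    x_best, e_best, v_best = x.copy(), e_cur, v_cur
    decay = (params.t_end / params.t_start) ** (1.0 / max(params.max_moves - 1, 1))
    temp = params.t_start
    for _ in range(params.max_moves):
        gi = int(rng.integers(len(engine.blocks)))
        idx = engine.blocks[gi]
        direction = None
        if restraints and rng.random() < 0.5:
            # pull the chosen glycerol toward the worst-violated restraint's
            # fibroin group
            dists = engine.restraint_distances(x)
            gaps = dists - np.array([ub for _, _, ub in engine.restraints])
            wi = int(np.argmax(gaps))
            if gaps[wi] > 0:
                ia, ib, _ = engine.restraints[wi]
                sf_side = ib if np.isin(ib, engine.sf_idx).all() else ia
                centroid = x[idx].mean(axis=0)
                sf_xyz = x[sf_side]
                target = sf_xyz[np.argmin(
                    np.linalg.norm(sf_xyz - centroid, axis=1))]
                direction = target - centroid
        new_block = _random_rigid_move(rng, x[idx], params.max_translation,
                                       params.max_rotation_deg, direction)
        # hard clash guard: reject moves that worsen the closest contact
        # below the refinement floor
        trial = x.copy()
        trial[idx] = new_block
        d_new = engine.min_contact(trial, gi)
        if d_new < REFINE_CLASH_FLOOR and d_new < engine.min_contact(x, gi):
            continue
        e_new, v_new = engine.energy(trial, params.clash_weight)
        accept = e_new <= e_cur or rng.random() < math.exp(
            min((e_cur - e_new) / max(temp, 1e-12), 0.0))
        if accept:
            x, e_cur, v_cur = trial, e_new, v_new
            if (v_cur, e_cur) < (v_best, e_best):
                x_best, e_best, v_best = x.copy(), e_cur, v_cur
        temp *= decay
    best = model.copy()
    best.set_coords(x_best)
    best.provenance["refined"] = {"seed": params.seed,
                                  "max_moves": params.max_moves,
                                  "energy": e_best,
                                  "violations": v_best}
    return best


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _to_atom_array(model: ComplexModel):
    import biotite.structure as struc

    n = len(model.atoms)
    arr = struc.AtomArray(n)
    arr.coord = model.coords
    arr.chain_id = model.atoms["chain_id"].to_numpy(dtype="U4")
    arr.res_id = model.atoms["res_id"].to_numpy(dtype=int)
    arr.res_name = model.atoms["res_name"].to_numpy(dtype="U5")
    arr.atom_name = model.atoms["atom_name"].to_numpy(dtype="U6")
    arr.element = model.atoms["element"].to_numpy(dtype="U2")
    arr.hetero = (model.atoms["res_name"] == "GOL").to_numpy()
    if model.cell is not None:
        arr.box = model.cell.vectors()
    return arr


def write_pdb(models: ComplexModel | list[ComplexModel], path) -> None:
    """Write one model (or a multi-MODEL candidate set) as PDB.

    Glycerols are written as GOL het-residues; the unit cell, when set,
    goes into the CRYST1 record.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(models, ComplexModel):
        structure = _to_atom_array(models)
    else:
        arrays = [_to_atom_array(m) for m in models]
        structure = struc.stack(arrays)
        if models[0].cell is not None:
            structure.box = np.repeat(models[0].cell.vectors()[None],
                                      len(arrays), axis=0)
    pdb = PDBFile()
    pdb.set_structure(structure)
    pdb.write(path)


def _cell_from_box(box: np.ndarray | None) -> UnitCell | None:
    if box is None:
        return None
    import biotite.structure as struc

    a, b, c, al, be, ga = struc.unitcell_from_vectors(box)
    return UnitCell(float(a), float(b), float(c),
                    float(np.degrees(al)), float(np.degrees(be)),
                    float(np.degrees(ga)))


def read_pdb(path) -> list[ComplexModel]:
    """Read a (possibly multi-MODEL) PDB into ComplexModel objects.

    Molecule tags are recovered from the residue name (GOL -> GLYC, else
    SF).  Malformed ATOM/HETATM records raise a ValueError naming the line.
    """
    from biotite.structure.io.pdb import PDBFile

    with open(path) as fh:
        lines = fh.readlines()
    for ln, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(f"{path}: malformed coordinate record at "
                                 f"line {ln}") from None
    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)
    cell = _cell_from_box(stack.box[0] if stack.box is not None else None)
    models = []
    for arr in stack:
        df = pd.DataFrame({
            "atom_name": arr.atom_name,
            "element": arr.element,
            "res_name": arr.res_name,
            "res_id": arr.res_id,
            "chain_id": arr.chain_id,
            "mol": np.where(arr.res_name == "GOL", "GLYC", "SF"),
            "x": arr.coord[:, 0], "y": arr.coord[:, 1], "z": arr.coord[:, 2],
        })
        models.append(ComplexModel(df, cell=cell))
    return models
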