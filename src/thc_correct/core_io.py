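"""On-disk formats and validated domain containers.

A *system archive* is an HDF5 file holding everything needed to run the
correlation-energy pipeline for one closed-shell species: active orbital
energies, the occupied/virtual partition, three-index density-fitting (DF)
factors per orbital-pair block, and parent-grid collocation matrices.
Frozen-core orbitals are dropped at archive creation time; nothing stored
here refers to them except the ``n_frozen`` bookkeeping count.

Reaction schemes travel as plain CSV with columns
``reaction_id,species_id,nu`` where ``nu`` is the signed stoichiometric
number (reactants negative, products positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

#: kcal/mol per Hartree, used for reporting only; all internal energies are Hartree.
HARTREE_TO_KCAL = 627.5094740631

FORMAT_VERSION = "thc-correct/1"

PAIR_TYPES = ("oo", "ov", "vv")


class ValidationError(ValueError):
    """An input violates a documented container invariant."""


@dataclass
class OrbitalSystem:
    """Active-space orbital data for one closed-shell species.

    ``eps`` holds the active orbital energies in Hartree, occupied block
    first (ascending), then virtuals (ascending).  ``n_valence`` is the
    number of active (valence) electrons, ``2 * n_occ_active`` for a
    closed shell.
    """

    species_id: str
    eps: np.ndarray
    n_occ_active: int
    n_vir: int
    n_frozen: int = 0
    e_scf: float = 0.0

    def __post_init__(self):
        self.eps = np.asarray(self.eps, dtype=float)
        self.validate()

    @property
    def n_valence(self) -> int:
        return 2 * self.n_occ_active

    @property
    def eps_occ(self) -> np.ndarray:
        return self.eps[: self.n_occ_active]

    @property
    def eps_vir(self) -> np.ndarray:
        return self.eps[self.n_occ_active :]

    @property
    def gap(self) -> float:
        """HOMO-LUMO gap (Hartree)."""
        return float(self.eps_vir.min() - self.eps_occ.max())

    @property
    def span(self) -> float:
        """Total eigenvalue span over active orbitals (Hartree)."""
        return float(self.eps.max() - self.eps.min())

    def validate(self) -> None:
        if self.n_occ_active < 1:
            raise ValidationError("n_occ_active must be >= 1")
        if self.n_vir < 1:
            raise ValidationError("n_vir must be >= 1")
        if self.n_frozen < 0:
            raise ValidationError("n_frozen must be >= 0")
        if self.eps.ndim != 1 or self.eps.size != self.n_occ_active + self.n_vir:
            raise ValidationError("eps length must equal n_occ_active + n_vir")
        if not np.all(np.isfinite(self.eps)):
            raise ValidationError("eps contains non-finite entries")
        if self.eps_occ.max() >= self.eps_vir.min():
            raise ValidationError("positive HOMO-LUMO gap required (eps)")


@dataclass
class DFTensors:
    """Three-index DF factors ``B[p, q, J]`` per orbital-pair block.

    The block arrays share the auxiliary dimension ``n_aux``; ``B_oo`` and
    ``B_vv`` are symmetric in their first two indices (real orbitals).
    The two-electron integrals they induce,
    ``g[pq, rs] = sum_J B[p,q,J] B[r,s,J]``, form a PSD Gram matrix over
    combined pair indices by construction.
    """

    B_oo: np.ndarray
    B_ov: np.ndarray
    B_vv: np.ndarray

    def __post_init__(self):
        self.B_oo = np.asarray(self.B_oo, dtype=float)
        self.B_ov = np.asarray(self.B_ov, dtype=float)
        self.B_vv = np.asarray(self.B_vv, dtype=float)
        self.validate()

    @property
    def n_aux(self) -> int:
        return self.B_ov.shape[2]

    def block(self, pair_type: str) -> np.ndarray:
        return {"oo": self.B_oo, "ov": self.B_ov, "vv": self.B_vv}[pair_type]

    def validate(self) -> None:
        for name, arr in (("B_oo", self.B_oo), ("B_ov", self.B_ov), ("B_vv", self.B_vv)):
            if arr.ndim != 3:
                raise ValidationError(f"{name} must be a 3-index array")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite entries")
        if not (self.B_oo.shape[2] == self.B_ov.shape[2] == self.B_vv.shape[2]):
            raise ValidationError("auxiliary dimension mismatch across DF blocks")
        if self.B_oo.shape[0] != self.B_oo.shape[1]:
            raise ValidationError("B_oo must be square in orbital indices")
        if self.B_vv.shape[0] != self.B_vv.shape[1]:
            raise ValidationError("B_vv must be square in orbital indices")
        for name, arr in (("B_oo", self.B_oo), ("B_vv", self.B_vv)):
            if not np.allclose(arr, arr.transpose(1, 0, 2), atol=1e-10):
                raise ValidationError(f"{name} must be symmetric in orbital indices")


@dataclass
class Collocation:
    """Molecular-orbital values at grid points for one pair type.

    ``X_left``/``X_right`` are (orbital, grid-point) matrices for the left
    and right orbital of the pair; for ``ov`` the left block is occupied
    and the right virtual.
    """

    pair_type: str
    X_left: np.ndarray
    X_right: np.ndarray
    grid_coords: np.ndarray | None = None

    def __post_init__(self):
        self.X_left = np.asarray(self.X_left, dtype=float)
        self.X_right = np.asarray(self.X_right, dtype=float)
        if self.grid_coords is not None:
            self.grid_coords = np.asarray(self.grid_coords, dtype=float)
        self.validate()

    @property
    def n_grid(self) -> int:
        return self.X_left.shape[1]

    def subset(self, idx: np.ndarray) -> "Collocation":
        """Sub-collocation at the given grid-point indices (pruning)."""
        coords = None if self.grid_coords is None else self.grid_coords[idx]
        return Collocation(self.pair_type, self.X_left[:, idx], self.X_right[:, idx], coords)

    def validate(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise ValidationError(f"pair_type must be one of {PAIR_TYPES}")
        if self.X_left.ndim != 2 or self.X_right.ndim != 2:
            raise ValidationError("collocation matrices must be 2-D")
        if self.X_left.shape[1] != self.X_right.shape[1]:
            raise ValidationError("X_left and X_right must share the grid dimension")
        if self.X_left.shape[1] < 1:
            raise ValidationError("n_grid must be >= 1")
        if not (np.all(np.isfinite(self.X_left)) and np.all(np.isfinite(self.X_right))):
            raise ValidationError("collocation contains non-finite entries")


@dataclass
class ReactionScheme:
    """A reaction as (species_id, signed stoichiometric number) members."""

    reaction_id: str
    members: list = field(default_factory=list)

    def __post_init__(self):
        self.members = [(str(s), int(n)) for s, n in self.members]
        self.validate()

    @property
    def nu_abs_sum(self) -> int:
        return sum(abs(n) for _, n in self.members)

    def validate(self) -> None:
        nus = [n for _, n in self.members]
        if not any(n < 0 for n in nus):
            raise ValidationError(f"reaction {self.reaction_id}: no reactant (negative nu)")
        if not any(n > 0 for n in nus):
            raise ValidationError(f"reaction {self.reaction_id}: no product (positive nu)")
        if self.nu_abs_sum < 2:
            raise ValidationError(f"reaction {self.reaction_id}: sum |nu| must be >= 2")


def write_system_archive(system: OrbitalSystem, df: DFTensors,
                         grids: dict | list, path) -> None:
    """Write one species to an HDF5 system archive.

    ``grids`` maps pair type to parent :class:`Collocation` (a list of
    collocations is also accepted).  All containers are validated before
    anything touches disk.
    """
    if not isinstance(grids, dict):
        grids = {g.pair_type: g for g in grids}
    system.validate()
    df.validate()
    if set(grids) != set(PAIR_TYPES):
        raise ValidationError(f"grids must cover pair types {PAIR_TYPES}")
    for pt, g in grids.items():
        g.validate()
        if g.pair_type != pt:
            raise ValidationError(f"grid stored under {pt} has pair_type {g.pair_type}")
    n_o, n_v = system.n_occ_active, system.n_vir
    shapes = {"oo": (n_o, n_o), "ov": (n_o, n_v), "vv": (n_v, n_v)}
    for pt, (nl, nr) in shapes.items():
        if df.block(pt).shape[:2] != (nl, nr):
            raise ValidationError(f"B_{pt} orbital shape mismatch with system")
        g = grids[pt]
        if g.X_left.shape[0] != nl or g.X_right.shape[0] != nr:
            raise ValidationError(f"grid {pt} orbital dimension mismatch with system")

    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        meta.attrs["species_id"] = system.species_id
        orb = f.create_group("orbitals")
        orb.create_dataset("eps", data=system.eps)
        orb.attrs["n_occ_active"] = system.n_occ_active
        orb.attrs["n_vir"] = system.n_vir
        orb.attrs["n_frozen"] = system.n_frozen
        orb.attrs["e_scf"] = system.e_scf
        dfg = f.create_group("df")
        for pt in PAIR_TYPES:
            dfg.create_dataset(f"B_{pt}", data=df.block(pt))
        gg = f.create_group("grid")
        for pt in PAIR_TYPES:
            sub = gg.create_group(pt)
            sub.create_dataset("X_left", data=grids[pt].X_left)
            sub.create_dataset("X_right", data=grids[pt].X_right)
            if grids[pt].grid_coords is not None:
                sub.create_dataset("coords", data=grids[pt].grid_coords)


def read_system_archive(path):
    """Read a system archive; returns ``(OrbitalSystem, DFTensors, grids)``."""
    with h5py.File(path, "r") as f:
        version = f["meta"].attrs["format_version"]
        if version != FORMAT_VERSION:
            raise ValidationError(f"unsupported archive format {version!r}")
        orb = f["orbitals"]
        system = OrbitalSystem(
            species_id=str(f["meta"].attrs["species_id"]),
            eps=orb["eps"][()],
            n_occ_active=int(orb.attrs["n_occ_active"]),
            n_vir=int(orb.attrs["n_vir"]),
            n_frozen=int(orb.attrs["n_frozen"]),
            e_scf=float(orb.attrs["e_scf"]),
        )
        df = DFTensors(*(f["df"][f"B_{pt}"][()] for pt in PAIR_TYPES))
        grids = {}
        for pt in PAIR_TYPES:
            sub = f["grid"][pt]
            coords = sub["coords"][()] if "coords" in sub else None
            grids[pt] = Collocation(pt, sub["X_left"][()], sub["X_right"][()], coords)
    return system, df, grids


def read_reactions(path) -> list:
    """Parse a reaction-scheme CSV into validated :class:`ReactionScheme` s.

    Schemes are grouped by ``reaction_id`` with member (row) order
    preserved.  Errors carry the offending line number (1-based, header
    is line 1).
    """
    table = pd.read_csv(path, dtype=str)
    expected = ["reaction_id", "species_id", "nu"]
    if list(table.columns) != expected:
        raise ValidationError(
            f"reaction CSV columns must be {expected}, got {list(table.columns)}")
    members: dict[str, list] = {}
    for pos, row in enumerate(table.itertuples(index=False)):
        line = pos + 2
        try:
            nu = int(row.nu)
        except (TypeError, ValueError):
            raise ValidationError(f"line {line}: non-integer nu {row.nu!r}") from None
        members.setdefault(row.reaction_id, []).append((row.species_id, nu))
    schemes = []
    for rid, mem in members.items():
        try:
            schemes.append(ReactionScheme(rid, mem))
        except ValidationError as exc:
            first = table.index[table["reaction_id"] == rid][0] + 2
            raise ValidationError(f"line {first}: {exc}") from None
    return schemes


def write_reactions(schemes, path) -> None:
    rows = [(s.reaction_id, sp, nu) for s in schemes for sp, nu in s.members]
    pd.DataFrame(rows, columns=["reaction_id", "species_id", "nu"]).to_csv(path, index=False)
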