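"""Conformer pools, geometric observables and fold / halogen-bond classification.

A :class:`Conformer` is one rigid model of the peptide: an ordered list of
labelled atoms with cartesian coordinates in angstrom.  Pools of conformers
are read from multi-model PDB files (parsed with Biopython) or from the
package's extended XYZ dialect (documented in :func:`read_xyz_pool`).

Observables derived per conformer — interproton distances, backbone
dihedrals, C-H bond unit vectors and the I...O halogen-bond geometry — feed
the NAMFIS and RDC ensemble fits.  :func:`classify_fold` assigns each
conformer a folded/unfolded label from type-II' beta-turn dihedral windows,
the mean interstrand C-alpha distance and cross-strand hydrogen-bond
proxies, plus a halogen-bonded flag from the I...O distance/angle criterion.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import VDW_SUM_IO, XB_ANGLE_MIN
from .geometry import angle, dihedral, distance, unit_vector

__all__ = [
    "Atom",
    "Conformer",
    "ObservableSpec",
    "ObservableSet",
    "FoldCriteria",
    "FoldLabel",
    "read_conformer_pool",
    "write_conformer_pool",
    "compute_observables",
    "classify_fold",
    "classify_conformer",
]


class ConformerError(ValueError):
    """Raised for malformed conformer input."""


@dataclass(frozen=True)
class Atom:
    label: str
    residue_index: int
    residue_name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class Conformer:
    """One model of the peptide: labelled 3-D coordinates."""

    model_id: int
    atoms: list[Atom]
    _index: dict[str, Atom] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ConformerError(
                f"model {self.model_id}: duplicate atom labels {dupes}"
            )
        for a in self.atoms:
            if not all(math.isfinite(v) for v in a.xyz):
                raise ConformerError(
                    f"model {self.model_id}: non-finite coordinates for {a.label}"
                )
        # synthetic chains must carry a complete backbone per residue
        by_res: dict[int, set[str]] = {}
        for a in self.atoms:
            by_res.setdefault(a.residue_index, set()).add(a.label)
        for resi, labs in by_res.items():
            need = {f"N{resi}", f"CA{resi}", f"C{resi}"}
            if not need <= labs:
                raise ConformerError(
                    f"model {self.model_id}: residue {resi} lacks backbone atoms "
                    f"{sorted(need - labs)}"
                )
        object.__setattr__(self, "_index", {a.label: a for a in self.atoms})

    def xyz(self, label: str) -> np.ndarray:
        try:
            return np.asarray(self._index[label].xyz, float)
        except KeyError:
            raise ConformerError(
                f"atom {label!r} absent from model {self.model_id}"
            ) from None

    def has_atom(self, label: str) -> bool:
        return label in self._index

    @property
    def residue_indices(self) -> list[int]:
        return sorted({a.residue_index for a in self.atoms})


# --------------------------------------------------------------------------
# observables
# --------------------------------------------------------------------------


@dataclass
class ObservableSpec:
    """Which observables to compute from a conformer.

    distances
        iterable of (label_a, label_b) atom pairs.
    dihedrals
        mapping dihedral name -> four atom labels.
    ch_vectors
        mapping vector name -> (carbon label, proton label); the stored unit
        vector points from the bonded heavy atom to the proton.
    xb_triple
        optional (C, I, O) labels for the halogen-bond geometry, where C is
        the carbon covalently bonded to the iodine.
    """

    distances: Sequence[tuple[str, str]] = ()
    dihedrals: Mapping[str, tuple[str, str, str, str]] = field(default_factory=dict)
    ch_vectors: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    xb_triple: tuple[str, str, str] | None = None


@dataclass
class ObservableSet:
    distances: dict[tuple[str, str], float]
    dihedrals: dict[str, float]
    ch_vectors: dict[str, np.ndarray]
    xb: tuple[float, float] | None  # (I...O distance A, C-I...O angle deg)


def compute_observables(conf: Conformer, spec: ObservableSpec) -> ObservableSet:
    """Measure the requested distances, dihedrals, vectors and XB geometry."""
    dists = {
        (a, b): distance(conf.xyz(a), conf.xyz(b)) for a, b in spec.distances
    }
    dihs = {
        name: dihedral(*(conf.xyz(l) for l in labels))
        for name, labels in spec.dihedrals.items()
    }
    vecs = {
        name: unit_vector(conf.xyz(heavy), conf.xyz(proton))
        for name, (heavy, proton) in spec.ch_vectors.items()
    }
    xb = None
    if spec.xb_triple is not None:
        c_lab, i_lab, o_lab = spec.xb_triple
        d_io = distance(conf.xyz(i_lab), conf.xyz(o_lab))
        ang = angle(conf.xyz(c_lab), conf.xyz(i_lab), conf.xyz(o_lab))
        xb = (d_io, ang)
    return ObservableSet(distances=dists, dihedrals=dihs, ch_vectors=vecs, xb=xb)


# --------------------------------------------------------------------------
# fold classification
# --------------------------------------------------------------------------


@dataclass
class FoldCriteria:
    """Configurable folded / halogen-bonded classification criteria.

    Defaults describe a ten-residue beta-hairpin with a type II' turn at
    residues 5-6 (D-Pro - Gly), an XB donor iodine on residue 3 and an
    ether-oxygen acceptor on residue 8.
    """

    # (phi_center, phi_halfwidth, psi_center, psi_halfwidth) per turn residue
    turn_windows: Mapping[int, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            5: (60.0, 40.0, -120.0, 40.0),
            6: (-90.0, 40.0, 0.0, 40.0),
        }
    )
    # residue pairs whose CA-CA distances define interstrand proximity
    strand_pairs: Sequence[tuple[int, int]] = ((2, 9), (3, 8), (4, 7))
    ca_mean_max: float = 5.5
    # cross-strand H-bond proxies as (N residue, O residue) pairs
    hbond_pairs: Sequence[tuple[int, int]] = ((2, 9), (4, 7), (7, 4), (9, 2))
    hbond_max: float = 3.5
    hbond_min_count: int = 2
    # halogen-bond geometry
    xb_triple: tuple[str, str, str] | None = ("CB3", "I3", "OE8")
    xb_distance_max: float = VDW_SUM_IO
    xb_angle_min: float = XB_ANGLE_MIN

    def observable_spec(self) -> ObservableSpec:
        """Observables needed to evaluate these criteria."""
        dihedrals: dict[str, tuple[str, str, str, str]] = {}
        for resi in self.turn_windows:
            dihedrals[f"phi{resi}"] = (
                f"C{resi - 1}", f"N{resi}", f"CA{resi}", f"C{resi}"
            )
            dihedrals[f"psi{resi}"] = (
                f"N{resi}", f"CA{resi}", f"C{resi}", f"N{resi + 1}"
            )
        distances = [(f"CA{i}", f"CA{j}") for i, j in self.strand_pairs]
        distances += [(f"N{i}", f"O{j}") for i, j in self.hbond_pairs]
        return ObservableSpec(
            distances=distances, dihedrals=dihedrals, xb_triple=self.xb_triple
        )


@dataclass
class FoldLabel:
    folded: bool
    halogen_bonded: bool
    criteria_report: dict[str, tuple[bool, float]]


def _in_window(value: float, center: float, halfwidth: float) -> bool:
    delta = (value - center + 180.0) % 360.0 - 180.0
    return abs(delta) <= halfwidth


def classify_fold(obs: ObservableSet, cfg: FoldCriteria | None = None) -> FoldLabel:
    """Deterministic folded / halogen-bonded labelling of one conformer.

    Folded requires all three criteria: turn dihedrals inside the configured
    type-II' windows, mean interstrand CA-CA distance below threshold, and at
    least ``hbond_min_count`` cross-strand N...O contacts below threshold.
    Halogen bonded requires I...O shorter than the vdW sum and a C-I...O
    angle at iodine above the configured floor.
    """
    cfg = cfg or FoldCriteria()
    report: dict[str, tuple[bool, float]] = {}

    turn_ok = True
    for resi, (phi0, dphi, psi0, dpsi) in cfg.turn_windows.items():
        for name, center, hw in (
            (f"phi{resi}", phi0, dphi),
            (f"psi{resi}", psi0, dpsi),
        ):
            if name not in obs.dihedrals:
                raise ConformerError(f"fold criteria need dihedral {name!r}")
            val = obs.dihedrals[name]
            ok = _in_window(val, center, hw)
            report[f"turn_{name}"] = (ok, val)
            turn_ok &= ok

    ca_dists = []
    for i, j in cfg.strand_pairs:
        key = (f"CA{i}", f"CA{j}")
        if key not in obs.distances:
            raise ConformerError(f"fold criteria need distance {key}")
        ca_dists.append(obs.distances[key])
    if ca_dists:
        ca_mean = float(np.mean(ca_dists))
        ca_ok = ca_mean <= cfg.ca_mean_max
    else:  # criterion not configured
        ca_mean, ca_ok = float("nan"), True
    report["interstrand_ca_mean"] = (ca_ok, ca_mean)

    n_hb = 0
    for i, j in cfg.hbond_pairs:
        key = (f"N{i}", f"O{j}")
        if key not in obs.distances:
            raise ConformerError(f"fold criteria need distance {key}")
        if obs.distances[key] <= cfg.hbond_max:
            n_hb += 1
    hb_ok = n_hb >= cfg.hbond_min_count
    report["hbond_count"] = (hb_ok, float(n_hb))

    folded = turn_ok and ca_ok and hb_ok

    halogen_bonded = False
    if cfg.xb_triple is not None:
        if obs.xb is None:
            raise ConformerError("fold criteria configure an XB triple but the "
                                 "observable set carries no XB geometry")
        d_io, ang = obs.xb
        d_ok = d_io < cfg.xb_distance_max
        a_ok = ang >= cfg.xb_angle_min
        report["xb_distance"] = (d_ok, d_io)
        report["xb_angle"] = (a_ok, ang)
        halogen_bonded = d_ok and a_ok

    return FoldLabel(folded=folded, halogen_bonded=halogen_bonded,
                     criteria_report=report)


def classify_conformer(conf: Conformer, cfg: FoldCriteria | None = None) -> FoldLabel:
    """Convenience: compute the needed observables, then classify."""
    cfg = cfg or FoldCriteria()
    spec = cfg.observable_spec()
    if spec.xb_triple is not None and not all(
        conf.has_atom(l) for l in spec.xb_triple
    ):
        spec = ObservableSpec(spec.distances, spec.dihedrals, {}, None)
        cfg_noxb = FoldCriteria(**{**cfg.__dict__, "xb_triple": None})
        return classify_fold(compute_observables(conf, spec), cfg_noxb)
    return classify_fold(compute_observables(conf, spec), cfg)


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------


def _element_from_label(label: str) -> str:
    for ch in label:
        if ch.isalpha():
            return ch.upper()
    raise ConformerError(f"cannot infer element from label {label!r}")


def read_conformer_pool(path: str | Path, format: str | None = None) -> list[Conformer]:
    """Read a conformer pool from a multi-model PDB or extended XYZ file.

    The format is inferred from the suffix when not given.  Model order is
    preserved; atom elements missing from the file are inferred from the
    first alphabetic character of the atom label.
    """
    path = Path(path)
    fmt = format or ("xyz" if path.suffix.lower() == ".xyz" else "pdb")
    if fmt == "pdb":
        return _read_pdb_pool(path)
    if fmt == "xyz":
        return read_xyz_pool(path)
    raise ValueError(f"unknown conformer pool format {fmt!r}")


def _read_pdb_pool(path: Path) -> list[Conformer]:
    text = path.read_text()
    if "MODEL" in text and "ENDMDL" not in text:
        first = next(
            line for line in text.splitlines() if line.startswith("MODEL")
        )
        raise ConformerError(
            f"MODEL record without matching ENDMDL (first open model: "
            f"{first.split()[-1]})"
        )
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pool", str(path))
    pool: list[Conformer] = []
    for model in structure:
        atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                for at in res:
                    name = at.get_name().strip()
                    resi = res.get_id()[1]
                    # unique labels are NAME+resSeq in this dialect
                    label = f"{name}{resi}"
                    elem = (at.element or "").strip() or _element_from_label(name)
                    x, y, z = at.get_coord()
                    atoms.append(
                        Atom(label, resi, res.get_resname().strip(),
                             elem, (float(x), float(y), float(z)))
                    )
        try:
            pool.append(Conformer(model_id=model.id + 1, atoms=atoms))
        except ConformerError as exc:
            raise ConformerError(f"model {model.id + 1}: {exc}") from exc
    if not pool:
        raise ConformerError(f"no models found in {path}")
    return pool


def write_conformer_pool(pool: Iterable[Conformer], path: str | Path,
                         format: str | None = None) -> None:
    """Write a pool as multi-model PDB or extended XYZ (suffix-inferred)."""
    path = Path(path)
    fmt = format or ("xyz" if path.suffix.lower() == ".xyz" else "pdb")
    if fmt == "pdb":
        path.write_text(_pdb_text(pool))
    elif fmt == "xyz":
        path.write_text(_xyz_text(pool))
    else:
        raise ValueError(f"unknown conformer pool format {fmt!r}")


def _pdb_name(label: str, resi: int) -> str:
    # strip the trailing residue number from the unique label
    suffix = str(resi)
    return label[: -len(suffix)] if label.endswith(suffix) else label


def _pdb_text(pool: Iterable[Conformer]) -> str:
    buf = io.StringIO()
    for n, conf in enumerate(pool, start=1):
        buf.write(f"MODEL     {n:4d}\n")
        atoms = sorted(conf.atoms, key=lambda a: a.residue_index)
        for serial, a in enumerate(atoms, start=1):
            name = _pdb_name(a.label, a.residue_index)
            pdb_name = f" {name:<3s}" if len(name) < 4 else name[:4]
            buf.write(
                f"ATOM  {serial:5d} {pdb_name} {a.residue_name[:3]:>3s} A"
                f"{a.residue_index:4d}    "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}\n"
            )
        buf.write("ENDMDL\n")
    buf.write("END\n")
    return buf.getvalue()


def _xyz_text(pool: Iterable[Conformer]) -> str:
    """Extended XYZ: per frame a count line, a comment line ``model=<id>``,
    then ``element x y z label residue_index residue_name`` per atom."""
    buf = io.StringIO()
    for conf in pool:
        buf.write(f"{len(conf.atoms)}\n")
        buf.write(f"model={conf.model_id}\n")
        for a in conf.atoms:
            buf.write(
                f"{a.element:<2s} {a.xyz[0]:12.6f} {a.xyz[1]:12.6f} "
                f"{a.xyz[2]:12.6f} {a.label} {a.residue_index} {a.residue_name}\n"
            )
    return buf.getvalue()


def read_xyz_pool(path: str | Path) -> list[Conformer]:
    """Read the extended XYZ dialect written by :func:`write_conformer_pool`."""
    lines = Path(path).read_text().splitlines()
    pool: list[Conformer] = []
    i = 0
    model_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        model_no += 1
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ConformerError(
                f"model {model_no}: expected atom count, got {lines[i]!r}"
            ) from None
        comment = lines[i + 1].strip()
        model_id = model_no
        if comment.startswith("model="):
            model_id = int(comment.split("=", 1)[1])
        atoms: list[Atom] = []
        block = lines[i + 2 : i + 2 + natoms]
        if len(block) < natoms:
            raise ConformerError(f"model {model_no}: truncated XYZ block")
        for line in block:
            parts = line.split()
            if len(parts) < 7:
                raise ConformerError(
                    f"model {model_no}: malformed XYZ atom line {line!r}"
                )
            elem, x, y, z, label, resi, resn = parts[:7]
            atoms.append(
                Atom(label, int(resi), resn, elem.upper(),
                     (float(x), float(y), float(z)))
            )
        pool.append(Conformer(model_id=model_id, atoms=atoms))
        i += 2 + natoms
    if not pool:
        raise ConformerError(f"no models found in {path}")
    return pool
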