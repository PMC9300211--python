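"""Synthetic ground-truth generators for every input the pipeline consumes.

The generators emulate the study system: a ten-residue peptide in a
two-state folding equilibrium (~50 % folded near room temperature) between
a type-II' beta-hairpin — capable of an intramolecular I...O halogen bond
between a donor iodine on residue 3 and an ether-oxygen acceptor on residue
8 — and an unfolded coil.  Chains are built by internal-coordinate
(natural-extension-of-reference-frame) placement with fixed ideal bond
lengths and angles, so requested backbone dihedrals are realised exactly.
The melt, NOE build-up and RDC generators draw from the same two-state /
r^-6 / Saupe-tensor models the analysis modules invert, with configurable
noise; every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as k
from .conformers import Atom, Conformer, FoldCriteria, classify_conformer
from .geometry import dihedral, nerf_place, unit_vector
from .melting import two_state_shift
from .restraints import GEMINAL_R_REF

__all__ = [
    "GeneratorConfig",
    "build_chain",
    "hairpin_template",
    "extended_dihedrals",
    "generate_pool",
    "simulate_melt",
    "simulate_noe",
    "simulate_rdc",
    "default_distance_pairs",
    "default_rdc_vectors",
]

#: default residue naming for the ten-residue synthetic chain; residue 5 is
#: D-configured (the turn D-Pro stand-in), 3 carries the iodine, 8 the ether O
DEFAULT_SEQUENCE = ("GLY", "THR", "FEI", "GLU", "DPR",
                    "GLY", "LYS", "HSM", "SER", "GLY")

#: default Saupe 5-vector (S_yy, S_zz, S_xy, S_xz, S_yz); with D_max =
#: -22700 Hz it produces RDCs of roughly -60..+60 Hz over generic vectors,
#: matching a weak lyotropic alignment
DEFAULT_SAUPE = np.array([-8.0e-4, 1.6e-3, 6.0e-4, -9.0e-4, 4.0e-4])


@dataclass
class GeneratorConfig:
    """Stated world for all synthetic datasets.  ``seed`` is mandatory."""

    seed: int
    n_residues: int = 10
    xb_donor_residue: int = 3
    xb_acceptor_residue: int = 8
    n_folded: int = 10
    n_unfolded: int = 10
    dihedral_jitter: float = 8.0  # deg, around the folded template
    xb_fraction: float = 0.55  # share of folded conformers built halogen-bonded
    # two-state melt truth (unfolding convention)
    tm: float = 274.0  # K
    dhm: float = 23_900.0  # J/mol
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(218.0, 349.0, 10.0))
    shift_noise: float = 0.0  # ppm (1 sigma)
    n_protons: int = 10
    # NOE build-up truth
    mixing_times: np.ndarray = field(
        default_factory=lambda: np.arange(0.1, 0.71, 0.1))
    buildup_curvature: float = 0.0  # kappa in I = sigma tau (1 - kappa tau)
    intensity_noise: float = 0.0  # relative (1 sigma)
    sigma_ref: float = 0.02  # intensity/s at the geminal reference pair
    # RDC truth
    saupe: np.ndarray = field(default_factory=lambda: DEFAULT_SAUPE.copy())
    rdc_noise: float = 0.0  # Hz (1 sigma) on 1T

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("shift_noise", "intensity_noise", "rdc_noise",
                     "dihedral_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.t_grid = np.asarray(self.t_grid, float)
        self.mixing_times = np.asarray(self.mixing_times, float)
        self.saupe = np.asarray(self.saupe, float)


# --------------------------------------------------------------------------
# chain building
# --------------------------------------------------------------------------


def extended_dihedrals(n_residues=10):
    """(phi, psi, omega) per residue for a fully extended strand."""
    return [(-120.0, 120.0, 180.0)] * n_residues


def hairpin_template(n_residues=10):
    """Folded-template dihedrals: beta strands flanking a type-II' turn.

    The turn sits at residues n//2 and n//2 + 1 (5-6 for the default
    ten-residue chain) with ideal II' angles (60, -120) / (-90, 0); strand
    residues use antiparallel-sheet values.  The strand values were tuned
    once so the built chain satisfies the default fold criteria (interstrand
    CA distances, cross-strand N...O contacts and an I...O distance inside
    the vdW sum) and then frozen.
    """
    t1 = n_residues // 2
    dihedrals = []
    for i in range(1, n_residues + 1):
        if i == t1 - 1:
            dihedrals.append((-123.0, 141.0, 180.0))
        elif i == t1:
            dihedrals.append((64.0, -90.0, 180.0))
        elif i == t1 + 1:
            dihedrals.append((-80.0, 3.0, 180.0))
        elif i == t1 + 2:
            dihedrals.append((-128.0, 133.0, 180.0))
        else:
            dihedrals.append((-123.0, 133.0, 180.0))
    return dihedrals


def build_chain(dihedrals, sequence=None, xb_donor=3, xb_acceptor=8,
                model_id=1, d_chirality_residues=None) -> Conformer:
    """Build a peptide conformer from backbone dihedrals by NeRF placement.

    ``dihedrals`` is one (phi, psi, omega) triple per residue; phi of the
    first and psi/omega of the last residue are not realisable and are
    ignored.  Each residue gets backbone N, CA, C, O, amide H, HA, a
    pseudo side-chain CB and a geminal HB1/HB2 methylene pair; the XB donor
    residue carries an iodine on CB and the acceptor residue an ether
    oxygen OE placed along the CB(donor)->CB(acceptor) axis, so the
    halogen-bond geometry follows from the backbone fold.
    """
    dihedrals = list(dihedrals)
    n = len(dihedrals)
    if n < 2:
        raise ValueError("need at least 2 residues")
    seq = list(sequence) if sequence is not None else \
        [DEFAULT_SEQUENCE[i % len(DEFAULT_SEQUENCE)] for i in range(n)]
    if len(seq) != n:
        raise ValueError("sequence length must match the dihedral list")
    d_res = set(d_chirality_residues) if d_chirality_residues is not None \
        else ({n // 2} if n >= 6 else set())

    npos = [None] * (n + 1)
    capos = [None] * (n + 1)
    cpos = [None] * (n + 1)
    # residue 1 placed explicitly in the xy-plane
    npos[1] = np.zeros(3)
    capos[1] = np.array([k.BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - k.ANGLE_N_CA_C)
    cpos[1] = capos[1] + k.BOND_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        phi_next, _, _ = dihedrals[i]
        _, psi_i, omega_i = dihedrals[i - 1]
        npos[i + 1] = nerf_place(npos[i], capos[i], cpos[i],
                                 k.BOND_C_N, k.ANGLE_CA_C_N, psi_i)
        capos[i + 1] = nerf_place(capos[i], cpos[i], npos[i + 1],
                                  k.BOND_N_CA, k.ANGLE_C_N_CA, omega_i)
        cpos[i + 1] = nerf_place(cpos[i], npos[i + 1], capos[i + 1],
                                 k.BOND_CA_C, k.ANGLE_N_CA_C, phi_next)

    atoms: list[Atom] = []

    def add(label, resi, element, xyz):
        atoms.append(Atom(label, resi, seq[resi - 1], element,
                          (float(xyz[0]), float(xyz[1]), float(xyz[2]))))

    for i in range(1, n + 1):
        phi_i = dihedrals[i - 1][0]
        psi_i = dihedrals[i - 1][1]
        add(f"N{i}", i, "N", npos[i])
        add(f"CA{i}", i, "C", capos[i])
        add(f"C{i}", i, "C", cpos[i])
        # carbonyl O anti to the next amide nitrogen
        o = nerf_place(npos[i], capos[i], cpos[i], k.BOND_C_O,
                       k.ANGLE_CA_C_O, psi_i + 180.0)
        add(f"O{i}", i, "O", o)
        # amide H trans to CA across the C'(i-1)-N bond
        if i > 1:
            h = nerf_place(capos[i], cpos[i - 1], npos[i], k.BOND_N_H,
                           k.ANGLE_C_N_H, 180.0)
        else:
            h = nerf_place(cpos[i], capos[i], npos[i], k.BOND_N_H,
                           k.ANGLE_C_N_H, 60.0)
        add(f"H{i}", i, "H", h)
        # CA branches: HA and CB at +-120 deg from the C' branch; the sign
        # choice sets the chirality (L default, flipped for D residues)
        ref = cpos[i - 1] if i > 1 else cpos[i] + np.array([0.0, 0.0, 1.0])
        branch = 120.0 if i not in d_res else -120.0
        ha = nerf_place(ref, npos[i], capos[i], k.BOND_C_H,
                        k.ANGLE_N_CA_HA, phi_branch(phi_i, i, n, -branch))
        cb = nerf_place(ref, npos[i], capos[i], k.BOND_CA_CB,
                        k.ANGLE_N_CA_CB, phi_branch(phi_i, i, n, branch))
        add(f"HA{i}", i, "H", ha)
        add(f"CB{i}", i, "C", cb)
        for j, chi in ((1, 60.0), (2, 180.0)):
            hb = nerf_place(npos[i], capos[i], cb, k.BOND_C_H,
                            k.ANGLE_CA_CB_HB, chi)
            add(f"HB{j}{i}", i, "H", hb)

    conf_atoms = {a.label: np.asarray(a.xyz) for a in atoms}
    if xb_donor is not None and xb_acceptor is not None and \
            xb_donor <= n and xb_acceptor <= n:
        cb_d = conf_atoms[f"CB{xb_donor}"]
        cb_a = conf_atoms[f"CB{xb_acceptor}"]
        u = unit_vector(cb_d, cb_a)
        iod = cb_d + k.BOND_C_I * u
        add(f"I{xb_donor}", xb_donor, "I", iod)
        add(f"OE{xb_acceptor}", xb_acceptor, "O", cb_a - k.BOND_C_OE * u)

    return Conformer(model_id=model_id, atoms=atoms)


def phi_branch(phi, i, n, offset):
    """Branch dihedral for CA substituents, referenced like phi itself."""
    # the branch torsion is measured in the same frame as the C' placement,
    # so HA/CB sit at phi -/+ 120 degrees
    return phi + offset if 1 < i else offset


def measured_dihedrals(conf: Conformer, n_residues) -> list:
    """Read back (phi, psi, omega) per residue from a built chain."""
    out = []
    for i in range(1, n_residues + 1):
        phi = psi = omega = np.nan
        if i > 1:
            phi = dihedral(conf.xyz(f"C{i - 1}"), conf.xyz(f"N{i}"),
                           conf.xyz(f"CA{i}"), conf.xyz(f"C{i}"))
        if i < n_residues:
            psi = dihedral(conf.xyz(f"N{i}"), conf.xyz(f"CA{i}"),
                           conf.xyz(f"C{i}"), conf.xyz(f"N{i + 1}"))
            omega = dihedral(conf.xyz(f"CA{i}"), conf.xyz(f"C{i}"),
                             conf.xyz(f"N{i + 1}"), conf.xyz(f"CA{i + 1}"))
        out.append((phi, psi, omega))
    return out


# --------------------------------------------------------------------------
# pool generation
# --------------------------------------------------------------------------

#: random-coil phi/psi sampling basins: (weight, phi_mu, phi_sd, psi_mu, psi_sd)
COIL_BASINS = ((0.6, -120.0, 25.0, 130.0, 25.0),
               (0.4, -70.0, 20.0, -35.0, 20.0))


def _coil_dihedrals(rng, n_residues):
    dihedrals = []
    for _ in range(n_residues):
        w = rng.random()
        basin = COIL_BASINS[0] if w < COIL_BASINS[0][0] else COIL_BASINS[1]
        _, pm, ps, sm, ss = basin
        dihedrals.append((rng.normal(pm, ps), rng.normal(sm, ss), 180.0))
    return dihedrals


def _with_xb_geometry(conf: Conformer, rng, donor, acceptor, bonded: bool,
                      deterministic: bool = False) -> Conformer:
    """Re-place the acceptor OE to realise (or break) the XB geometry.

    For a halogen-bonded conformer OE is positioned at a sampled I...O
    distance in (2.9, 3.4) A and C-I...O angle in (145, 175) deg (fixed at
    3.15 A / 160 deg when *deterministic*); otherwise it is attached to the
    acceptor CB pointing away from the iodine, which pushes I...O beyond
    the vdW sum.
    """
    iod = conf.xyz(f"I{donor}")
    cb_d = conf.xyz(f"CB{donor}")
    cb_a = conf.xyz(f"CB{acceptor}")
    if bonded:
        if deterministic:
            d_io, theta, az = 3.15, np.radians(160.0), 0.0
        else:
            d_io = rng.uniform(2.9, 3.4)
            theta = np.radians(rng.uniform(145.0, 175.0))
            az = rng.uniform(0.0, 2.0 * np.pi)
        v = unit_vector(iod, cb_d)  # towards the covalent carbon
        # orthonormal frame around v
        aux = np.array([1.0, 0.0, 0.0])
        if abs(v @ aux) > 0.9:
            aux = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(v, aux)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(v, e1)
        w = (np.cos(theta) * v
             + np.sin(theta) * (np.cos(az) * e1 + np.sin(az) * e2))
        oe = iod + d_io * w
    else:
        oe = cb_a + k.BOND_C_OE * unit_vector(iod, cb_a)
    resn = next(a.residue_name for a in conf.atoms
                if a.residue_index == acceptor)
    atoms = [a for a in conf.atoms if a.label != f"OE{acceptor}"]
    atoms.append(Atom(f"OE{acceptor}", acceptor, resn, "O",
                      (float(oe[0]), float(oe[1]), float(oe[2]))))
    return Conformer(model_id=conf.model_id, atoms=atoms)


def generate_pool(cfg: GeneratorConfig):
    """Conformer pool with truth labels.

    Folded conformers are the hairpin template plus Gaussian dihedral
    jitter; a configured fraction of them is built halogen bonded.
    Unfolded conformers draw coil dihedrals from broad beta and alpha
    basins.  Returns ``(pool, truth)`` with truth a DataFrame indexed by
    model id carrying boolean ``folded`` and ``halogen_bonded`` columns.

    Reproducible: the pool is a pure function of the config (incl. seed).
    """
    if cfg.n_folded + cfg.n_unfolded == 0:
        raise ValueError("pool must contain at least one conformer")
    rng = np.random.default_rng(cfg.seed)
    template = hairpin_template(cfg.n_residues)
    criteria = FoldCriteria(
        xb_triple=(f"CB{cfg.xb_donor_residue}", f"I{cfg.xb_donor_residue}",
                   f"OE{cfg.xb_acceptor_residue}"))
    pool, rows = [], []
    model_id = 0
    n_xb = int(round(cfg.xb_fraction * cfg.n_folded))
    # folded conformers are drawn from the folded basin: jittered template
    # dihedrals, rejection-sampled against the fold criteria (force-field
    # pools are likewise relaxed back into their basin after perturbation)
    for j in range(cfg.n_folded):
        model_id += 1
        for _attempt in range(200):
            jit = rng.normal(0.0, cfg.dihedral_jitter,
                             size=(cfg.n_residues, 2)) \
                if cfg.dihedral_jitter > 0 else np.zeros((cfg.n_residues, 2))
            dihedrals = [(p + jit[i, 0], s + jit[i, 1], o)
                         for i, (p, s, o) in enumerate(template)]
            conf = build_chain(dihedrals, xb_donor=cfg.xb_donor_residue,
                               xb_acceptor=cfg.xb_acceptor_residue,
                               model_id=model_id)
            conf = _with_xb_geometry(conf, rng, cfg.xb_donor_residue,
                                     cfg.xb_acceptor_residue,
                                     bonded=j < n_xb,
                                     deterministic=cfg.dihedral_jitter == 0)
            lab = classify_conformer(conf, criteria)
            if lab.folded and lab.halogen_bonded == (j < n_xb):
                break
        else:
            raise RuntimeError("could not sample a folded conformer; "
                               "dihedral_jitter is likely too large")
        pool.append(conf)
        rows.append({"model_id": model_id, "folded": True,
                     "halogen_bonded": j < n_xb})
    for _ in range(cfg.n_unfolded):
        model_id += 1
        for _attempt in range(200):
            conf = build_chain(_coil_dihedrals(rng, cfg.n_residues),
                               xb_donor=cfg.xb_donor_residue,
                               xb_acceptor=cfg.xb_acceptor_residue,
                               model_id=model_id)
            conf = _with_xb_geometry(conf, rng, cfg.xb_donor_residue,
                                     cfg.xb_acceptor_residue, bonded=False)
            if not classify_conformer(conf, criteria).folded:
                break
        else:
            raise RuntimeError("could not sample an unfolded conformer")
        pool.append(conf)
        rows.append({"model_id": model_id, "folded": False,
                     "halogen_bonded": False})
    truth = pd.DataFrame(rows).set_index("model_id")
    return pool, truth


def pool_truth_populations(truth: pd.DataFrame, folded_share=0.5,
                           n_active=None) -> pd.Series:
    """A ground-truth population vector with a given folded share.

    With ``n_active=None`` populations spread uniformly within the folded
    and unfolded blocks.  With an integer ``n_active``, only the first
    ``n_active`` conformers of each block carry population, split in a
    geometric 2:1 cascade — the sparse, few-conformer ensembles that
    NAMFIS-style deconvolutions typically resolve.
    """
    folded = truth["folded"].to_numpy(bool)
    p = np.zeros(len(truth))

    def block(mask, share):
        idx = np.where(mask)[0]
        if len(idx) == 0:
            return
        if n_active is None:
            p[idx] = share / len(idx)
        else:
            m = min(n_active, len(idx))
            w = 0.5 ** np.arange(m)
            p[idx[:m]] = share * w / w.sum()

    block(folded, folded_share)
    block(~folded, 1.0 - folded_share)
    return pd.Series(p / p.sum(), index=truth.index, name="population")


# --------------------------------------------------------------------------
# observable simulation
# --------------------------------------------------------------------------


def simulate_melt(cfg: GeneratorConfig, tm=None, dhm=None,
                  proton_labels=None):
    """Variable-temperature shift table from the two-state model.

    Per-proton terminal shifts are drawn once from the seed (delta_U in
    7.2-8.6 ppm, shift change 0.15-0.5 ppm with random sign); all protons
    share (T_m, dH_m).  Returns ``(table, truth)`` with the table a
    DataFrame (index T in K, one column per proton, ppm).
    """
    tm = cfg.tm if tm is None else tm
    dhm = cfg.dhm if dhm is None else dhm
    rng = np.random.default_rng(cfg.seed)
    labels = list(proton_labels) if proton_labels is not None else \
        [f"H{i + 1}" for i in range(cfg.n_protons)]
    data = {}
    truth_terminals = {}
    for lab in labels:
        du = rng.uniform(7.2, 8.6)
        delta = rng.uniform(0.15, 0.5) * rng.choice([-1.0, 1.0])
        df = du + delta
        clean = two_state_shift(cfg.t_grid, du, df, tm, dhm)
        noisy = clean + rng.normal(0.0, cfg.shift_noise, size=clean.shape) \
            if cfg.shift_noise > 0 else clean
        data[lab] = noisy
        truth_terminals[lab] = (du, df)
    table = pd.DataFrame(data, index=pd.Index(cfg.t_grid, name="T_K"))
    truth = {"tm": tm, "dhm": dhm, "terminals": truth_terminals}
    return table, truth


def default_distance_pairs(cfg: GeneratorConfig):
    """Restrained proton pairs: sequential HA-H(N), cross-strand H(N)-H(N)
    and HA-HA contacts, plus the geminal reference methylene."""
    n = cfg.n_residues
    pairs = [(f"HA{i}", f"H{i + 1}") for i in range(1, n)]
    pairs += [(f"H{i}", f"H{n + 1 - i}") for i in range(2, n // 2 + 1)]
    pairs += [(f"HA{i}", f"HA{n + 1 - i}") for i in range(2, n // 2 + 1)]
    ref = (f"HB1{cfg.xb_donor_residue}", f"HB2{cfg.xb_donor_residue}")
    return pairs + [ref], ref


def simulate_noe(pool, populations, cfg: GeneratorConfig, pairs=None,
                 reference_pair=None):
    """NOE build-up tables from population-averaged r^-6 distances.

    Cross-relaxation rates scale as sigma_ref (r/r_ref)^-6 with the geminal
    reference pair fixed at 1.78 A; intensities follow
    ``I(tau) = sigma tau (1 - kappa tau)`` with multiplicative Gaussian
    noise.  Returns ``(table, true_distances)`` where the table holds one
    column per pair over the configured mixing times.
    """
    p = np.asarray(populations, float)
    if abs(p.sum() - 1.0) > 1e-6 or (p < -1e-12).any():
        raise ValueError("populations must lie on the simplex")
    if pairs is None:
        pairs, reference_pair = default_distance_pairs(cfg)
    if reference_pair is None:
        reference_pair = pairs[-1]
    rng = np.random.default_rng(cfg.seed)
    avg = {}
    for a, b in pairs:
        try:
            r_i = np.array([np.linalg.norm(c.xyz(a) - c.xyz(b)) for c in pool])
        except Exception as exc:
            raise KeyError(f"pair ({a}, {b}) absent from pool: {exc}") from exc
        avg[(a, b)] = float((p @ r_i**-6.0) ** (-1.0 / 6.0))
    r_ref = avg[reference_pair]
    tau = cfg.mixing_times
    cols = {}
    for pair, r in avg.items():
        sigma = cfg.sigma_ref * (r / GEMINAL_R_REF) ** -6.0
        clean = sigma * tau * (1.0 - cfg.buildup_curvature * tau)
        noise = rng.normal(1.0, cfg.intensity_noise, size=tau.shape) \
            if cfg.intensity_noise > 0 else 1.0
        cols[f"{pair[0]}/{pair[1]}"] = clean * noise
    table = pd.DataFrame(cols, index=pd.Index(tau, name="tau_s"))
    true_dist = pd.Series({f"{a}/{b}": r for (a, b), r in avg.items()},
                          name="r_true")
    return table, true_dist


def default_rdc_vectors(cfg: GeneratorConfig):
    """(label, heavy, proton_labels, n_h) C-H vectors for the RDC stage:
    backbone CA-HA of every residue plus every pseudo-side-chain CB
    methylene as a CH2 group (its effective RDC averages the two bonds)."""
    vecs = [(f"a{i}", f"CA{i}", (f"HA{i}",), 1)
            for i in range(1, cfg.n_residues + 1)]
    vecs += [(f"b{i}", f"CB{i}", (f"HB1{i}", f"HB2{i}"), 2)
             for i in range(1, cfg.n_residues + 1)]
    return vecs


def simulate_rdc(pool, populations, cfg: GeneratorConfig, vectors=None,
                 saupe=None):
    """RDC table (1J/1T pairs) from a known tensor and populations.

    For each vector the population-averaged design row (group-averaged for
    CHn) is contracted with the true Saupe tensor; scalar couplings are
    drawn per multiplicity from typical ranges (CH 140-170 Hz, CH2 sums
    255-295 Hz) and ``1T = 1J + n_H D`` plus Gaussian noise.  Returns
    ``(table, truth_dict)``; the table follows the text schema read by
    :func:`hairpinxb.rdc.read_rdc_table`.
    """
    from .rdc import design_rows_for_pool

    p = np.asarray(populations, float)
    saupe = cfg.saupe if saupe is None else np.asarray(saupe, float)
    if vectors is None:
        vectors = default_rdc_vectors(cfg)
    rng = np.random.default_rng(cfg.seed)
    design = design_rows_for_pool(pool, vectors)  # (n_conf, n_obs, 5)
    avg_rows = np.tensordot(p, design, axes=(0, 0))
    d_true_arr = k.DMAX_CH * avg_rows @ saupe
    rows = []
    truth_d = {}
    for (label, heavy, protons, n_h), d_true in zip(vectors, d_true_arr):
        truth_d[label] = float(d_true)
        if n_h == 1:
            j = rng.uniform(140.0, 170.0)
        elif n_h == 2:
            j = rng.uniform(255.0, 295.0)
        else:
            j = rng.uniform(375.0, 425.0)
        noise = rng.normal(0.0, cfg.rdc_noise) if cfg.rdc_noise > 0 else 0.0
        t = j + n_h * float(d_true) + noise
        rows.append({"label": label,
                     "multiplicity": "CH" if n_h == 1 else f"CH{n_h}",
                     "j": round(j, 2), "sigma_j": 0.5,
                     "t": round(t, 2),
                     "sigma_t": max(cfg.rdc_noise, 0.5)})
    table = pd.DataFrame(rows)
    truth = {"saupe": saupe, "d": truth_d,
             "populations": np.asarray(p, float)}
    return table, truth
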