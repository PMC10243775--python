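"""Synthetic ground-truth networks, source dynamics, sensor recordings and
longitudinal cohort scenarios.

Every stage of the connectivity pipeline is testable without real data:
this module emits sparse VAR(2) source models with known directed edges,
simulates beta-band-resonant source activity, projects it through a random
patch-coherent forward model, and assembles whole longitudinal cohorts
(patients with lesion sides and clinical score tables, controls with stable
networks) whose qualitative structure mirrors a minor-stroke recovery
study: reduced frontoparietal (FPC) involvement at the first visit that
normalizes by the second, and a visit-3 reduction of inter-hemispheric
reliance that is confined to the favourably recovering patients.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .recording import SensorRecording
from .source_model import SourceSpace, roi_classes

logger = logging.getLogger(__name__)

__all__ = [
    "VARModel",
    "CohortScenario",
    "GroundTruth",
    "make_var2_model",
    "simulate_source_activity",
    "make_forward_model",
    "simulate_recording",
    "make_cohort",
    "write_edge_lists",
    "read_edge_lists",
]


# --------------------------------------------------------------------------
# VAR(2) source models


@dataclass
class VARModel:
    """Second-order VAR source dynamics with patch-block sparsity.

    ``a1`` and ``a2`` are the lag-1 and lag-2 coefficient matrices over the
    scalar source channels; cross-patch coupling blocks are nonzero exactly
    on the ground-truth directed edge set.  ``q`` is the innovation
    covariance.
    """

    a1: np.ndarray
    a2: np.ndarray
    q: np.ndarray
    node_to_patch: np.ndarray
    edges: frozenset = field(default_factory=frozenset)

    @property
    def n_nodes(self) -> int:
        return self.a1.shape[0]

    @property
    def companion(self) -> np.ndarray:
        """Companion matrix [[A1, A2], [I, 0]] of the VAR(2) recursion."""
        n = self.n_nodes
        c = np.zeros((2 * n, 2 * n))
        c[:n, :n] = self.a1
        c[:n, n:] = self.a2
        c[n:, :n] = np.eye(n)
        return c

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion))))


def make_var2_model(
    source_space: SourceSpace,
    edge_set,
    coupling_strength: float = 0.35,
    seed: int = 0,
    *,
    fs: float = 50.0,
    osc_freq_range: tuple[float, float] = (15.0, 23.0),
    pole_radius_range: tuple[float, float] = (0.86, 0.94),
    lag2_coupling_scale: float = 0.5,
    innovation_sd_range: tuple[float, float] = (0.8, 1.2),
    target_radius: float = 0.95,
    max_shrink_steps: int = 200,
) -> VARModel:
    """Build a sparse stationary VAR(2) source model over a patch space.

    Each scalar component gets a stable AR(2) diagonal pair whose complex
    poles resonate in ``osc_freq_range`` Hz at sampling rate ``fs`` (beta
    band by default).  Directed cross-patch coupling blocks, dense at the
    component level and scaled by ``coupling_strength``, are placed exactly
    on ``edge_set``.  If the companion spectral radius exceeds
    ``target_radius`` all coefficients are repeatedly shrunk by 0.9 until
    it does not (raising after ``max_shrink_steps``).
    """
    if coupling_strength <= 0:
        raise ValueError("coupling_strength must be > 0")
    edges = frozenset((int(s), int(d)) for s, d in edge_set)
    for s, d in edges:
        if s == d:
            raise ValueError(f"self-pair ({s}, {d}) not allowed in edge_set")
        if not (0 <= s < source_space.n_patches and 0 <= d < source_space.n_patches):
            raise ValueError(f"edge ({s}, {d}) outside patch range")

    rng = np.random.default_rng(seed)
    node_to_patch = source_space.node_to_patch
    n = source_space.n_nodes
    a1 = np.zeros((n, n))
    a2 = np.zeros((n, n))

    # within-patch dynamics: independent beta-resonant AR(2) per component
    f0 = rng.uniform(*osc_freq_range, size=n)
    rad = rng.uniform(*pole_radius_range, size=n)
    omega = 2.0 * np.pi * f0 / fs
    np.fill_diagonal(a1, 2.0 * rad * np.cos(omega))
    np.fill_diagonal(a2, -(rad ** 2))

    # directed cross-patch blocks, dense at component level
    for s, d in sorted(edges):
        rows = np.flatnonzero(node_to_patch == d)
        cols = np.flatnonzero(node_to_patch == s)
        k = np.sqrt(len(rows) * len(cols))
        a1[np.ix_(rows, cols)] = rng.normal(size=(len(rows), len(cols))) * \
            coupling_strength / k
        a2[np.ix_(rows, cols)] = rng.normal(size=(len(rows), len(cols))) * \
            coupling_strength * lag2_coupling_scale / k

    q = np.diag(rng.uniform(*innovation_sd_range, size=n) ** 2)
    model = VARModel(a1=a1, a2=a2, q=q, node_to_patch=node_to_patch, edges=edges)

    for _ in range(max_shrink_steps):
        if model.spectral_radius <= target_radius:
            break
        model.a1 *= 0.9
        model.a2 *= 0.9
    else:
        raise RuntimeError(
            f"could not reach companion spectral radius <= {target_radius} "
            f"within {max_shrink_steps} shrink steps")

    # Enforce genuinely weak coupling: a cross coefficient sitting at the
    # receiver's resonance can amplify the donor's variance by an order of
    # magnitude, which both violates the weak-coupling premise and (via a
    # near-deterministic driven node) turns indirect chains into genuine
    # latent-state predictors.  Shrink the cross blocks until no node's
    # stationary variance exceeds twice its uncoupled baseline.
    def _stationary_vars(m):
        Qb = np.zeros((2 * n, 2 * n))
        Qb[:n, :n] = m.q
        cov = linalg.solve_discrete_lyapunov(m.companion, Qb)
        return np.diag(cov)[:n]

    a1d, a2d, qd = np.diag(model.a1), np.diag(model.a2), np.diag(model.q)
    base = qd * (1 - a2d) / ((1 + a2d) * ((1 - a2d) ** 2 - a1d ** 2))
    cross = ~np.eye(n, dtype=bool)
    if edges:
        for _ in range(60):
            if np.max(_stationary_vars(model) / base) <= 2.0:
                break
            model.a1[cross] *= 0.8
            model.a2[cross] *= 0.8

    # balance stationary variances toward 1 through the innovation
    # variances only; coefficients stay untouched
    qdiag = qd.copy()
    for _ in range(8):
        Qb = np.zeros((2 * n, 2 * n))
        Qb[:n, :n] = np.diag(qdiag)
        cov = linalg.solve_discrete_lyapunov(model.companion, Qb)
        v = np.diag(cov)[:n]
        if np.max(np.abs(v - 1.0)) < 0.05:
            break
        qdiag = np.maximum(qdiag / np.clip(v, 0.25, None), 0.02)
    model.q = np.diag(qdiag)
    return model


def simulate_source_activity(
    model: VARModel,
    n_samples: int,
    burn_in: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Simulate the VAR(2) recursion x_t = A1 x_{t-1} + A2 x_{t-2} + w_t.

    ``w_t`` is Gaussian with covariance ``model.q``; the first ``burn_in``
    samples are discarded so the returned nodes x samples matrix is
    approximately a draw from the stationary distribution.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if model.spectral_radius >= 1.0:
        raise ValueError("model is not stationary (companion spectral "
                         f"radius {model.spectral_radius:.4f} >= 1)")
    rng = np.random.default_rng(seed)
    n = model.n_nodes
    total = n_samples + burn_in
    chol = np.linalg.cholesky(model.q + 1e-15 * np.eye(n))
    w = chol @ rng.standard_normal((n, total))
    x = np.zeros((n, total + 2))
    for t in range(total):
        x[:, t + 2] = model.a1 @ x[:, t + 1] + model.a2 @ x[:, t] + w[:, t]
    return x[:, 2 + burn_in:]


# --------------------------------------------------------------------------
# Forward model and sensor recordings


def make_forward_model(
    source_space: SourceSpace,
    n_sensors: int = 157,
    seed: int = 0,
    patch_coherence: float = 0.7,
    patch_overlap: float = 0.15,
) -> np.ndarray:
    """Random gain matrix (sensors x nodes) with patch-coherent columns.

    Each patch gets a base topography drawn from a random orthonormal set
    and perturbed by ``patch_overlap`` worth of shared Gaussian direction,
    so distinct patches are near-orthogonal (as lead fields of distant
    cortical patches are at realistic sensor counts) without being exactly
    so.  Columns belonging to one patch mix the base topography with
    weight ``patch_coherence`` so they are mutually correlated.  All
    columns are unit-normalized.

    When there are more patches than sensors the orthonormal construction
    is infeasible and fully random base topographies are used instead.
    """
    if n_sensors < 2:
        raise ValueError("need at least 2 sensors")
    rng = np.random.default_rng(seed)
    n_patches = source_space.n_patches
    if n_sensors >= n_patches:
        basis, _ = np.linalg.qr(rng.standard_normal((n_sensors, n_patches)))
    else:
        basis = rng.standard_normal((n_sensors, n_patches))
        basis /= np.linalg.norm(basis, axis=0)
    cols = []
    for pi, p in enumerate(source_space.patches):
        u = basis[:, pi] + patch_overlap * rng.standard_normal(n_sensors) \
            / np.sqrt(n_sensors)
        u /= np.linalg.norm(u)
        if p.k_components == 1:
            cols.append(u)
            continue
        for _ in range(p.k_components):
            w = rng.standard_normal(n_sensors)
            w /= np.linalg.norm(w)
            g = patch_coherence * u + np.sqrt(1.0 - patch_coherence ** 2) * w
            cols.append(g / np.linalg.norm(g))
    return np.column_stack(cols)


def simulate_recording(
    sources: np.ndarray,
    gain: np.ndarray,
    noise_sd: float,
    fs: float,
    metadata: dict | None = None,
    seed: int = 0,
) -> SensorRecording:
    """Project sources through the gain and add isotropic sensor noise.

    ``noise_sd`` is the absolute standard deviation of the additive
    Gaussian noise on every channel.
    """
    sources = np.asarray(sources, dtype=float)
    if gain.shape[1] != sources.shape[0]:
        raise ValueError(
            f"gain has {gain.shape[1]} columns but sources has "
            f"{sources.shape[0]} rows")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    y = gain @ sources
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(y.shape)
    return SensorRecording(data=y, fs=fs, **(metadata or {}))


# --------------------------------------------------------------------------
# Longitudinal cohort scenarios


@dataclass
class CohortScenario:
    """Parameters of a longitudinal two-group connectivity scenario.

    The defaults encode the study conditions the pipeline is meant to
    emulate: six patients and four controls over three visits; patients
    start with a frontoparietal connectivity deficit (low share of edges
    touching FPC) that normalizes to the control level by visit 2; the
    directional balance of patients' inter-hemispheric edges starts
    contra->ipsi dominated and flips to ipsi->contra by visit 2; at visit 3
    only the ``favourable_ids`` patients reduce their inter-hemispheric
    reliance.  Controls keep one edge distribution across all visits.
    """

    n_patients: int = 6
    n_controls: int = 4
    visits: int = 3
    #: target fraction of edges touching FPC, per group per visit.  With
    #: ~19% of patches in FPC, random pairing gives ~0.34; controls sit
    #: just above that and patients' visit-1 deficit is large, as the
    #: qualitative pattern being emulated demands.
    fpc_link_fraction: dict = field(default_factory=lambda: {
        "patient": (0.10, 0.38, 0.38),
        "control": (0.38, 0.38, 0.38),
    })
    #: per-visit share of patients' inter-hemispheric edges oriented
    #: ipsilesional -> contralesional
    ipsi_to_contra_bias: tuple = (0.30, 0.75, 0.75)
    #: patient ids whose visit-3 networks reduce inter-hemispheric reliance
    favourable_ids: tuple = ("patient_01", "patient_02", "patient_05")
    #: baseline share of inter-hemispheric edges, and the reduced share
    #: used by favourable patients at the final visit
    interhemi_fraction: float = 0.45
    favourable_final_interhemi: float = 0.18
    n_edges: int = 60
    coupling_strength: float = 0.35
    #: sensor noise scale, as a fraction of the noiseless sensor-signal RMS
    noise_sd: float = 0.25
    n_sensors: int = 157
    fs: float = 1000.0
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.visits < 2:
            raise ValueError("need at least 2 visits")
        for group, fracs in self.fpc_link_fraction.items():
            if len(fracs) != self.visits:
                raise ValueError(f"{group}: need one FPC fraction per visit")
            if any(not 0 <= f <= 1 for f in fracs):
                raise ValueError("FPC fractions must lie in [0, 1]")
        if any(not 0 <= b <= 1 for b in self.ipsi_to_contra_bias):
            raise ValueError("ipsi_to_contra_bias values must lie in [0, 1]")
        bad = set(self.favourable_ids) - set(self.patient_ids)
        if bad:
            raise ValueError(f"favourable_ids not in patient set: {bad}")

    @property
    def patient_ids(self) -> list[str]:
        return [f"patient_{i + 1:02d}" for i in range(self.n_patients)]

    @property
    def control_ids(self) -> list[str]:
        return [f"control_{i + 1:02d}" for i in range(self.n_controls)]


@dataclass
class GroundTruth:
    """Per-subject-per-visit generating edge sets plus subject labels.

    ``edges`` maps ``(subject_id, visit)`` to the frozenset of directed
    patch pairs of the generating model.  ``gains`` holds each subject's
    forward matrix (fixed across visits) so inference can be run on the
    generated recordings.
    """

    edges: dict
    group: dict
    lesion_hemisphere: dict
    gains: dict = field(default_factory=dict)

    def edge_set(self, subject_id: str, visit: int) -> frozenset:
        return self.edges[(subject_id, visit)]


def _pair_categories(space: SourceSpace, lesion: str | None):
    """Partition all ordered non-self patch pairs by FPC contact and,
    for patients, by inter-hemispheric direction."""
    classes = roi_classes(space)
    hemi = [p.hemisphere for p in space.patches]
    cats = {"fpc": {"intra": [], "ic": [], "ci": []},
            "non": {"intra": [], "ic": [], "ci": []}}
    for s in range(space.n_patches):
        for d in range(space.n_patches):
            if s == d:
                continue
            roi_key = "fpc" if ("FPC" in (classes[s], classes[d])) else "non"
            if hemi[s] == hemi[d]:
                hemi_key = "intra"
            elif lesion is None:
                hemi_key = "ic" if hemi[s] == "left" else "ci"
            else:
                hemi_key = "ic" if hemi[s] == lesion else "ci"
            cats[roi_key][hemi_key].append((s, d))
    return cats


def _sample_edges(rng, cats, n_edges, fpc_fraction, interhemi_fraction, bias):
    """Draw a directed edge set matching the target category shares.

    The number of FPC-touching edges is binomial around the target
    fraction, so category percentages vary across subjects the way
    independently sampled networks would (an exact quota would make some
    category shares deterministic).
    """
    n_fpc_avail = sum(len(v) for v in cats["fpc"].values())
    n_non_avail = sum(len(v) for v in cats["non"].values())
    target = fpc_fraction * n_edges
    if target > n_fpc_avail or n_edges - target > n_non_avail:
        raise ValueError(
            f"infeasible FPC fraction target {fpc_fraction:g} at "
            f"{n_edges} edges: only {n_fpc_avail} FPC-touching and "
            f"{n_non_avail} other candidate pairs exist")
    n_fpc = int(rng.binomial(n_edges, fpc_fraction))
    n_fpc = int(np.clip(n_fpc, max(0, n_edges - n_non_avail),
                        min(n_edges, n_fpc_avail)))
    out = []
    for roi_key, count in (("fpc", n_fpc), ("non", n_edges - n_fpc)):
        pools = cats[roi_key]
        pairs = pools["intra"] + pools["ic"] + pools["ci"]
        w = np.concatenate([
            np.full(len(pools["intra"]),
                    (1 - interhemi_fraction) / max(len(pools["intra"]), 1)),
            np.full(len(pools["ic"]),
                    interhemi_fraction * bias / max(len(pools["ic"]), 1)),
            np.full(len(pools["ci"]),
                    interhemi_fraction * (1 - bias) / max(len(pools["ci"]), 1)),
        ])
        w = w / w.sum()
        idx = rng.choice(len(pairs), size=count, replace=False, p=w)
        out.extend(pairs[i] for i in idx)
    return frozenset(out)


def _clinical_rows(rng, patient_id, lesion, favourable, visits):
    """Longitudinal clinical scores for one synthetic patient.

    All measures improve from visit 1 to visit 2; between visits 2 and 3
    every measure improves for favourable patients and declines for
    unfavourable ones, with margins large enough that the recovery
    classifier is decidable in practice (steps of at least 0.4 z-units
    against score noise of 0.05).
    """
    z_cols = ["hvlt", "verbal_fluency", "trail_making", "pegboard", "sdmt"]
    base = {c: rng.uniform(-2.5, -1.2) for c in z_cols}
    moca = int(rng.integers(21, 26))
    rows = []
    for visit in range(1, visits + 1):
        if visit == 2:
            for c in z_cols:
                base[c] += rng.uniform(0.5, 1.5)
            moca = min(30, moca + int(rng.integers(2, 4)))
        elif visit >= 3:
            step = 1.0 if favourable else -1.0
            for c in z_cols:
                base[c] += step * rng.uniform(0.4, 1.0)
            moca = int(np.clip(moca + (1 if favourable else -1), 0, 30))
        row = {
            "patient": patient_id,
            "visit": visit,
            "lesion_hemisphere": lesion,
            "nihss": int(rng.integers(0, 3)) if visit == 1 else 0,
            "mrs": int(rng.integers(0, 2)),
            "barthel": 100,
            "moca": moca,
        }
        for c in z_cols:
            row[c] = round(base[c] + rng.normal(scale=0.05), 3)
        rows.append(row)
    return rows


def make_cohort(scenario: CohortScenario, source_space: SourceSpace):
    """Generate a full longitudinal cohort.

    Returns ``(recordings, ground_truth, clinical_table)``: one
    :class:`~netgc.recording.SensorRecording` per subject per visit, the
    generating edge sets and forward matrices, and a per-patient-per-visit
    clinical score table shaped like the package's bundled reference
    cohort CSV.
    """
    rng = np.random.default_rng(scenario.seed)
    n_samples = int(round(scenario.duration_s * scenario.fs))

    recordings: list[SensorRecording] = []
    edges: dict = {}
    group: dict = {}
    lesion_map: dict = {}
    gains: dict = {}
    clinical_rows: list[dict] = []

    subjects = [(sid, "patient") for sid in scenario.patient_ids] + \
               [(sid, "control") for sid in scenario.control_ids]

    for s_idx, (sid, grp) in enumerate(subjects):
        sub_rng = np.random.default_rng(
            np.random.SeedSequence([scenario.seed, s_idx]))
        lesion = None
        if grp == "patient":
            lesion = "left" if sub_rng.random() < 0.5 else "right"
        group[sid] = grp
        lesion_map[sid] = lesion
        gain = make_forward_model(
            source_space, scenario.n_sensors,
            seed=int(sub_rng.integers(2 ** 31)))
        gains[sid] = gain
        cats = _pair_categories(source_space, lesion)

        for visit in range(1, scenario.visits + 1):
            fpc_frac = scenario.fpc_link_fraction[grp][visit - 1]
            if grp == "patient":
                bias = scenario.ipsi_to_contra_bias[visit - 1]
                ih = scenario.interhemi_fraction
                if visit == scenario.visits and sid in scenario.favourable_ids:
                    ih = scenario.favourable_final_interhemi
            else:
                bias, ih = 0.5, scenario.interhemi_fraction
            edge_set = _sample_edges(
                sub_rng, cats, scenario.n_edges, fpc_frac, ih, bias)
            edges[(sid, visit)] = edge_set

            model = make_var2_model(
                source_space, edge_set, scenario.coupling_strength,
                seed=int(sub_rng.integers(2 ** 31)), fs=scenario.fs)
            x = simulate_source_activity(
                model, n_samples, seed=int(sub_rng.integers(2 ** 31)))
            signal_rms = float(np.sqrt(np.mean((gain @ x) ** 2)))
            rec = simulate_recording(
                x, gain, scenario.noise_sd * signal_rms, scenario.fs,
                metadata={"subject_id": sid, "visit": visit, "group": grp,
                          "lesion_hemisphere": lesion},
                seed=int(sub_rng.integers(2 ** 31)))
            recordings.append(rec)

        if grp == "patient":
            clinical_rows.extend(_clinical_rows(
                sub_rng, sid, lesion, sid in scenario.favourable_ids,
                scenario.visits))

    clinical = pd.DataFrame(clinical_rows)
    gt = GroundTruth(edges=edges, group=group,
                     lesion_hemisphere=lesion_map, gains=gains)
    logger.info("generated cohort: %d recordings, %d patients, %d controls",
                len(recordings), scenario.n_patients, scenario.n_controls)
    return recordings, gt, clinical


# --------------------------------------------------------------------------
# Ground-truth serialization


def write_edge_lists(path: str | Path, ground_truth: GroundTruth) -> None:
    """Write ground-truth edges as TSV: src_patch, dst_patch, subject, visit."""
    rows = []
    for (sid, visit), edge_set in sorted(ground_truth.edges.items()):
        for s, d in sorted(edge_set):
            rows.append({"src_patch": s, "dst_patch": d,
                         "subject": sid, "visit": visit})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edge_lists(path: str | Path) -> dict:
    """Inverse of :func:`write_edge_lists` (edges only)."""
    df = pd.read_csv(path, sep="\t")
    out: dict = {}
    for (sid, visit), sub in df.groupby(["subject", "visit"]):
        out[(sid, int(visit))] = frozenset(
            zip(sub["src_patch"].astype(int), sub["dst_patch"].astype(int)))
    return out
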