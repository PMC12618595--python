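"""Synthetic cohorts with a known, recoverable SC->FC ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at matrix level only (no raw MEG/MRI):

* a fixed parcellation whose region centroids sit in two mirrored
  hemispheric ellipsoids, giving a shared Euclidean-distance (ED) matrix;
* per-subject structural connectomes over a cohort-shared
  distance-dependent backbone (edge probability proportional to
  exp(-d/lambda), calibrated to a target density), weighted with five
  variants that have visibly distinct distributions: heavy-tailed
  distance-decaying streamline counts (NS), volume-normalized counts (NSv),
  and three bounded microstructural weights (FA, iRD, FRt) drawn from a
  correlated copula;
* functional connectomes built from a linear law on the z-scored, negated
  communication predictors (SPL, SI, ED) of each subject's own SC, plus
  band-specific Gaussian edge noise (largest in delta, mirroring the
  empirically higher delta-band edge variability), affinely rescaled into
  [0, 1];
* a psychosis group generated from the *same* structural law, whose only
  divergence is an additive shift of the mapping coefficients -- the
  relationship between SC and FC is perturbed, the matrices are not.

Individuality knob
------------------
``individuality_sd`` controls how subject-specific the SC-FC relationship
is.  It jitters the per-subject mapping coefficients *and* scales the
subject-specific deviation of the structural network from the cohort
backbone (topology resampling probability and multiplicative edge-weight
jitter).  The structural component is essential: a per-subject refit absorbs
any coefficient change, so coefficient jitter alone cannot make a subject's
FC better predicted by their own SC than by someone else's.  At
``individuality_sd = 0`` subjects share a nearly identical connectome and
one mapping, so shuffling SC across subjects changes prediction accuracy by
less than ~0.02 -- the healthy-cohort null the analysis is calibrated
against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .analytical import build_predictors
from .core import (
    FC_BANDS,
    SC_VARIANTS,
    Cohort,
    ConnectivityMatrix,
    ConnectomeError,
    PanssScores,
    Parcellation,
    Subject,
    matrix_from_edges,
    upper_triangle,
    write_cohort,
)

BANDS = FC_BANDS


def _band_map(value) -> dict:
    if isinstance(value, dict):
        return {b: value[b] for b in BANDS}
    return {b: value for b in BANDS}


@dataclass
class GroundTruthMapping:
    """The linear SC->FC law the generator plants and the analysis recovers.

    For band b and edge e:
        fc_b(e) = b0_b + b_spl*(-z(SPL)) + b_si*(-z(SI)) + b_ed*(-z(ED)) + eps,
        eps ~ N(0, noise_sd_b),
    then affinely rescaled into [0, 1].  Predictors are z-scored within
    subject and negated: shorter paths, lower search information and shorter
    distances all mean stronger coupling.

    ``noise_sd`` defaults decrease from delta to beta, so delta FC is both
    the hardest band to predict and the one with the largest across-subject
    edge variability.  ``patient_shift`` is added to the psychosis group's
    coefficients: positive in delta (their delta FC follows the
    communication law *more* closely), negative in alpha/beta (weaker
    coupling), zero in theta.
    """

    intercept: dict = field(default_factory=lambda: _band_map(0.5))
    coefficients: dict = field(
        default_factory=lambda: {b: (0.4, 0.3, 0.2) for b in BANDS}
    )
    noise_sd: dict = field(
        default_factory=lambda: {
            "delta": 1.2,
            "theta": 0.8,
            "alpha": 0.5,
            "beta": 0.45,
        }
    )
    individuality_sd: float = 0.1
    patient_shift: dict = field(
        default_factory=lambda: {
            "delta": (0.25, 0.15, 0.10),
            "theta": (0.0, 0.0, 0.0),
            "alpha": (-0.25, -0.15, -0.10),
            "beta": (-0.25, -0.15, -0.10),
        }
    )

    def __post_init__(self):
        self.intercept = _band_map(self.intercept)
        self.noise_sd = _band_map(self.noise_sd)
        for b in BANDS:
            if self.noise_sd[b] < 0:
                raise ConnectomeError("noise_sd must be nonnegative")
        if self.individuality_sd < 0:
            raise ConnectomeError("individuality_sd must be nonnegative")

    @property
    def perturbed_bands(self) -> tuple:
        """Bands whose patient coefficients differ from the healthy ones."""
        return tuple(
            b for b in BANDS if any(abs(x) > 0 for x in self.patient_shift[b])
        )


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the study design: 126 healthy subjects aged 18-50 and
    5 psychosis patients aged 18-35, an 84-region parcellation, and a
    structural density of 0.35.
    """

    seed: int
    n_nodes: int = 84
    n_healthy: int = 126
    n_patients: int = 5
    healthy_age_range: tuple = (18.0, 50.0)
    patient_age_range: tuple = (18.0, 35.0)
    sc_density: float = 0.35
    mapping: GroundTruthMapping = field(default_factory=GroundTruthMapping)
    mapping_source: str = "FA"
    si_memory: bool = False
    panss_coupling: float = 0.0
    age_noise_slope: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ConnectomeError("a seed is mandatory")
        if self.n_nodes < 3:
            raise ConnectomeError("need at least 3 nodes")
        if self.n_healthy < 1 or self.n_patients < 0:
            raise ConnectomeError("subject counts must be positive")
        if not (0 < self.sc_density <= 1):
            raise ConnectomeError("sc_density must be in (0, 1]")
        if self.mapping_source not in SC_VARIANTS:
            raise ConnectomeError(f"mapping_source must be one of {SC_VARIANTS}")


# ---------------------------------------------------------------------------
# parcellation + ED
# ---------------------------------------------------------------------------


def generate_parcellation(n: int, seed: int) -> tuple[Parcellation, ConnectivityMatrix]:
    """Random centroids in two mirrored hemispheric ellipsoids; shared ED.

    Semi-axes (30, 45, 35) mm per hemisphere, hemisphere centers at
    x = +/-33 mm: roughly adult-head proportions.  ED(i, j) is the Euclidean
    distance between centroids, identical for every subject of a cohort.
    """
    if n < 3:
        raise ConnectomeError("parcellation needs at least 3 regions")
    rng = np.random.default_rng(seed)
    semi = np.array([30.0, 45.0, 35.0])
    n_left = (n + 1) // 2
    pts = []
    for n_hemi, x_sign in ((n_left, -1.0), (n - n_left, 1.0)):
        g = rng.standard_normal((n_hemi, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        radii = rng.uniform(0, 1, n_hemi) ** (1.0 / 3.0)
        ball = g * radii[:, None] * semi
        ball[:, 0] = x_sign * (np.abs(ball[:, 0]) + 33.0)
        pts.append(ball)
    centroids = np.vstack(pts)
    labels = tuple(
        f"{'lh' if i < n_left else 'rh'}_region_{i:03d}" for i in range(n)
    )
    parc = Parcellation(labels=labels, centroids=centroids)
    ed = squareform(pdist(centroids))
    return parc, ConnectivityMatrix(
        values=ed, kind="ED", variant=None, parcellation=parc
    )


# ---------------------------------------------------------------------------
# structural law: cohort-shared backbone + weight fields
# ---------------------------------------------------------------------------


@dataclass
class StructuralLaw:
    """Cohort-level edge fields from which every subject's SC is derived."""

    parcellation: Parcellation
    ed_edges: np.ndarray
    edge_prob: np.ndarray       # calibrated P(edge present | distance)
    backbone_u: np.ndarray      # shared uniform field defining the backbone
    log_ns_base: np.ndarray     # shared log streamline-count field
    micro_latent: np.ndarray    # (m, 3) correlated Gaussian field: FA, iRD, FRt
    volumes: np.ndarray         # per-region volumes for NS/v
    density: float

    # bounded-weight Beta parameters per variant: distinct means/shapes
    MICRO_PARAMS = {"FA": (12.0, 12.0), "iRD": (12.0, 8.0), "FRt": (9.0, 11.0)}
    MICRO_RHO = 0.6


def build_structural_law(
    parcellation: Parcellation,
    ed: ConnectivityMatrix,
    density: float,
    seed: int,
) -> StructuralLaw:
    rng = np.random.default_rng(seed)
    d = upper_triangle(ed.values)
    lam = float(np.mean(d)) / 2.0

    def mean_prob(c):
        return float(np.mean(np.minimum(1.0, c * np.exp(-d / lam))))

    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if mean_prob(mid) < density:
            lo = mid
        else:
            hi = mid
    c = np.sqrt(lo * hi)
    edge_prob = np.minimum(1.0, c * np.exp(-d / lam))

    m = d.size
    backbone_u = rng.uniform(0, 1, m)
    # log streamline count: decays with distance, heavy upper tail
    log_ns_base = 4.0 - 2.0 * d / np.mean(d) + 0.8 * rng.standard_normal(m)
    rho = StructuralLaw.MICRO_RHO
    shared = rng.standard_normal(m)
    micro_latent = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * (
        rng.standard_normal((m, 3))
    )
    volumes = np.exp(rng.normal(np.log(5000.0), 0.4, parcellation.n))
    return StructuralLaw(
        parcellation=parcellation,
        ed_edges=d,
        edge_prob=edge_prob,
        backbone_u=backbone_u,
        log_ns_base=log_ns_base,
        micro_latent=micro_latent,
        volumes=volumes,
        density=density,
    )


def _ensure_connected(present: np.ndarray, ed_edges: np.ndarray, n: int) -> np.ndarray:
    """Add the shortest absent edges until the graph is connected."""
    present = present.copy()
    iu, ju = np.triu_indices(n, k=1)
    for _ in range(n):
        adj = matrix_from_edges(present.astype(float), n)
        n_comp, labels = connected_components(adj > 0, directed=False)
        if n_comp == 1:
            return present
        cross = labels[iu] != labels[ju]
        candidates = np.flatnonzero(cross & ~present)
        best = candidates[np.argmin(ed_edges[candidates])]
        present[best] = True
    raise ConnectomeError("failed to connect the synthetic graph")


def generate_sc(
    ed: ConnectivityMatrix,
    subject_jitter: float,
    seed: int,
    law: StructuralLaw | None = None,
    density: float = 0.35,
    flip_prob: float = 0.0,
) -> dict[str, ConnectivityMatrix]:
    """One subject's five structural matrices (NS, NSv, FA, iRD, FRt).

    All five variants share one binary topology: the cohort backbone with a
    fraction ``flip_prob`` of edges re-drawn from the distance law for this
    subject, then patched to be connected.  Weights are the cohort base
    fields with per-subject multiplicative log-normal jitter of standard
    deviation ``subject_jitter``; bounded variants are clipped to (0, 1).
    """
    rng = np.random.default_rng(seed)
    if law is None:
        law = build_structural_law(ed.parcellation, ed, density, seed=rng.integers(2**31))
    n = law.parcellation.n
    m = law.ed_edges.size

    present = law.backbone_u < law.edge_prob
    if flip_prob > 0:
        redraw = rng.uniform(0, 1, m) < flip_prob
        present = np.where(redraw, rng.uniform(0, 1, m) < law.edge_prob, present)
    present = _ensure_connected(present, law.ed_edges, n)

    def jitter():
        if subject_jitter <= 0:
            return np.ones(m)
        return np.exp(subject_jitter * rng.standard_normal(m))

    out = {}
    ns = np.exp(law.log_ns_base) * jitter() * present
    out["NS"] = ns
    iu, ju = np.triu_indices(n, k=1)
    vol_sum = law.volumes[iu] + law.volumes[ju]
    out["NSv"] = ns / vol_sum * 1e4
    for k, variant in enumerate(("FA", "iRD", "FRt")):
        a, b = StructuralLaw.MICRO_PARAMS[variant]
        u = norm.cdf(law.micro_latent[:, k])
        base = beta_dist.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b)
        vals = np.clip(base * jitter(), 1e-4, 0.9999) * present
        out[variant] = vals
    return {
        variant: ConnectivityMatrix(
            values=matrix_from_edges(vals, n),
            kind="SC",
            variant=variant,
            parcellation=law.parcellation,
        )
        for variant, vals in out.items()
    }


# ---------------------------------------------------------------------------
# FC from the planted linear law
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_fc(
    sc_set: dict[str, ConnectivityMatrix],
    ed: ConnectivityMatrix,
    mapping: GroundTruthMapping,
    subject_coeffs: dict,
    seed: int,
    mapping_source: str = "FA",
    si_memory: bool = False,
    noise_scale: float = 1.0,
    diagnostics: dict | None = None,
) -> dict[str, ConnectivityMatrix]:
    """Four band FC matrices from the planted law on this subject's SC.

    ``subject_coeffs`` maps band -> (b_spl, b_si, b_ed), the realized
    (jittered, possibly patient-shifted) coefficients of this subject.
    ``noise_scale`` multiplies every band's noise SD (used for age effects).
    If a ``diagnostics`` dict is passed it receives, per band, the expected
    prediction error 1 - s/sqrt(s^2 + sd^2) implied by the realized signal
    standard deviation s.  Raises if the SC graph is disconnected.
    """
    rng = np.random.default_rng(seed)
    pred = build_predictors(sc_set[mapping_source], ed, si_memory=si_memory)
    neg_z = -np.column_stack(
        [_zscore(pred.spl), _zscore(pred.si), _zscore(pred.ed)]
    )
    n = ed.parcellation.n
    out = {}
    for band in BANDS:
        beta = np.asarray(subject_coeffs[band], dtype=float)
        sd = mapping.noise_sd[band] * noise_scale
        signal = neg_z @ beta
        y = mapping.intercept[band] + signal
        if diagnostics is not None:
            s_sd = signal.std(ddof=0)
            diagnostics[band] = 1.0 - s_sd / np.sqrt(s_sd**2 + sd**2)
        if sd > 0:
            y = y + rng.normal(0.0, sd, y.size)
        spread = y.std(ddof=0)
        if spread == 0:
            raise ConnectomeError(
                "degenerate FC: zero coefficients and zero noise"
            )
        # affine map into [0, 1]: the +/-7 SD span keeps every edge strictly
        # inside without clipping, and the subject's mean edge value is an
        # iid draw around 0.5 for both groups, so FC summary statistics
        # (e.g. total strength) vary across subjects but carry no group
        # signal -- the planted divergence lives in the mapping only
        level = 0.5 + 0.02 * rng.standard_normal()
        y = np.clip(level + (y - y.mean()) / (14.0 * spread), 0.0, 1.0)
        out[band] = ConnectivityMatrix(
            values=matrix_from_edges(y, n),
            kind="FC",
            variant=band,
            parcellation=ed.parcellation,
        )
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _structural_individuality(individuality_sd: float) -> tuple[float, float]:
    """(flip_prob, weight_jitter) implied by the individuality knob.

    Topology resampling scales purely with the knob, so at
    individuality_sd = 0 all subjects share the backbone topology and differ
    only by a small multiplicative weight jitter: shuffling SC across
    subjects then moves the analytical accuracy by less than 0.02 (the
    healthy-cohort null), while every subject's connectome stays distinct.
    """
    return 0.4 * individuality_sd, 0.01 + 0.6 * individuality_sd


def _draw_panss(rng: np.random.Generator) -> PanssScores:
    """Integer PANSS with components that sum to the total.

    Component minima follow the instrument (positive/negative >= 7,
    general >= 16, so total >= 30); totals land in 35-60, covering the
    moderate range observed in first-episode samples.
    """
    excess = int(rng.integers(5, 31))
    parts = rng.multinomial(excess, [0.25, 0.25, 0.5])
    return PanssScores(
        total=30 + excess,
        positive=7 + int(parts[0]),
        negative=7 + int(parts[1]),
        general=16 + int(parts[2]),
    )


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate a full cohort: parcellation, ED, SC x5, FC x4 per subject.

    Deterministic given the config (including its mandatory seed).  The
    realized per-subject coefficients and the generator settings are stored
    in ``cohort.extras['ground_truth']`` for recovery tests.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(6)
    parc, ed = generate_parcellation(config.n_nodes, int(seeds[0]))
    law = build_structural_law(parc, ed, config.sc_density, int(seeds[1]))
    rng = np.random.default_rng(int(seeds[2]))

    mapping = config.mapping
    flip_prob, weight_jitter = _structural_individuality(mapping.individuality_sd)

    subjects = []
    matrices = {}
    truth = {
        "config": {
            "n_nodes": config.n_nodes,
            "n_healthy": config.n_healthy,
            "n_patients": config.n_patients,
            "sc_density": config.sc_density,
            "mapping_source": config.mapping_source,
            "seed": config.seed,
            "individuality_sd": mapping.individuality_sd,
            "flip_prob": flip_prob,
            "weight_jitter": weight_jitter,
            "noise_sd": mapping.noise_sd,
            "intercept": mapping.intercept,
            "mean_coefficients": {b: list(mapping.coefficients[b]) for b in BANDS},
            "patient_shift": {b: list(mapping.patient_shift[b]) for b in BANDS},
            "age_noise_slope": config.age_noise_slope,
            "panss_coupling": config.panss_coupling,
        },
        "subjects": {},
    }

    groups = [("healthy", config.n_healthy, config.healthy_age_range)]
    if config.n_patients:
        groups.append(("psychosis", config.n_patients, config.patient_age_range))

    patient_rows = []
    for group, count, age_range in groups:
        for i in range(count):
            sid = f"{'h' if group == 'healthy' else 'p'}{i + 1:03d}"
            age = float(rng.uniform(*age_range))
            sc_seed = int(rng.integers(2**31))
            fc_seed = int(rng.integers(2**31))
            coeffs = {}
            for band in BANDS:
                beta = np.asarray(mapping.coefficients[band], dtype=float)
                beta = beta + mapping.individuality_sd * rng.standard_normal(3)
                if group == "psychosis":
                    beta = beta + np.asarray(mapping.patient_shift[band])
                coeffs[band] = tuple(float(x) for x in beta)
            sc_set = generate_sc(
                ed,
                subject_jitter=weight_jitter,
                seed=sc_seed,
                law=law,
                flip_prob=flip_prob,
            )
            lo, hi = config.healthy_age_range
            rel_age = (age - lo) / (hi - lo)
            noise_scale = max(0.1, 1.0 + config.age_noise_slope * (rel_age - 0.5))
            diagnostics: dict = {}
            fc_set = generate_fc(
                sc_set,
                ed,
                mapping,
                coeffs,
                seed=fc_seed,
                mapping_source=config.mapping_source,
                si_memory=config.si_memory,
                noise_scale=noise_scale,
                diagnostics=diagnostics,
            )
            panss = _draw_panss(rng) if group == "psychosis" else None
            subj = Subject(id=sid, age=age, group=group, panss=panss)
            if group == "psychosis":
                patient_rows.append((sid, diagnostics, panss))
            subjects.append(subj)
            matrices[(sid, "ED", None)] = ed
            for variant, mat in sc_set.items():
                matrices[(sid, "SC", variant)] = mat
            for band, mat in fc_set.items():
                matrices[(sid, "FC", band)] = mat
            truth["subjects"][sid] = {
                "group": group,
                "age": age,
                "coefficients": {b: list(coeffs[b]) for b in BANDS},
            }

    if config.panss_coupling > 0 and len(patient_rows) >= 2:
        subjects = _couple_panss(
            subjects, patient_rows, config.panss_coupling, rng, mapping
        )

    cohort = Cohort(
        subjects=subjects, matrices=matrices, parcellation=parc,
        extras={"ground_truth": truth},
    )
    return cohort


def _couple_panss(subjects, patient_rows, coupling, rng, mapping):
    """Reassign PANSS totals so severity tracks expected prediction error.

    Patients whose realized mapping carries the largest expected error in
    the weakened bands receive the highest totals; ``coupling`` in (0, 1]
    blends that deterministic ranking with the original random draw.
    """
    sids = [sid for sid, _, _ in patient_rows]
    # severity tracks the bands where patient coupling is weakened
    weakened = [b for b in BANDS if sum(mapping.patient_shift[b]) < 0]
    weakened = weakened or list(BANDS)
    attenuation = np.array(
        [sum(diag[b] for b in weakened) for _, diag, _ in patient_rows]
    )
    panss_list = [p for _, _, p in patient_rows]
    totals = np.array([p.total for p in panss_list])
    noise = rng.uniform(0, 1, len(sids))
    score = coupling * _rank01(attenuation) + (1 - coupling) * noise
    order = np.argsort(score)  # lowest score -> lowest total
    sorted_panss = [panss_list[i] for i in np.argsort(totals)]
    assignment = dict(zip([sids[i] for i in order], sorted_panss))
    out = []
    for s in subjects:
        if s.id in assignment:
            out.append(Subject(id=s.id, age=s.age, group=s.group,
                               panss=assignment[s.id]))
        else:
            out.append(s)
    return out


def _rank01(x: np.ndarray) -> np.ndarray:
    order = np.argsort(np.argsort(x))
    return order / max(1, len(x) - 1)


def write_synthetic_cohort(cohort: Cohort, directory) -> None:
    """Write the cohort directory plus ground_truth.json."""
    write_cohort(cohort, directory)
    truth = cohort.extras.get("ground_truth")
    if truth is not None:
        (Path(directory) / "ground_truth.json").write_text(
            json.dumps(truth, indent=1)
        )
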