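"""Synthetic two-group retinal expression studies with planted ground truth.

The generator emulates the structure the analysis pipeline assumes: a small
autopsy cohort of HIV-negative control retinae against lesion-free
HIV-positive samples plus two lesioned cohorts (cotton wool spots, CWS, and
intraretinal hemorrhages, IRH); tens of thousands of probes on a log2 scale
with several probes per gene; planted rod-gene upregulation (linear folds
around 2-5) and milder cone-gene downregulation (folds around -1.2 to -1.4);
a per-array smooth monotone intensity distortion for the normalizer to
remove; a low "undetected" floor mode for the detection threshold to find;
and donor times of death spanning the day.

Everything is driven by a single integer seed through one
``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection

__all__ = [
    "StudyDesign",
    "PlantedTruth",
    "default_design",
    "draw_tod",
    "generate_study",
    "probe_gene_map",
    "generate_geneset_collection",
    "with_set",
    "generate_qpcr",
]

# Fixed anchors of the log2 intensity scale used by the generator.
_FLOOR_MEAN = 2.2        # center of the undetected mode
_FLOOR_SD = 0.25
_EXPR_MEAN = 9.0         # center of the expressed mode
_EXPR_SD = 1.5
_EXPR_MIN, _EXPR_MAX = 6.5, 14.0
_DISTORT_LO, _DISTORT_HI = 0.0, 16.0   # domain of the per-array polynomial
_DISTORT_AMP = 0.5                     # max |shift| in log2 units


@dataclass(frozen=True)
class StudyDesign:
    """Sample counts and per-sample times of death for a synthetic study.

    ``n_probes`` counts *expressed* probes; the generator appends additional
    floor-level probes so that a fraction ``undetected_frac`` (argument of
    :func:`generate_study`) of all probes is removed by the detection filter.
    """

    n_neg: int
    n_pos: int
    n_cws: int = 0
    n_irh: int = 0
    n_probes: int = 2000
    probes_per_gene: int = 2
    tod: tuple | None = None    # hours since midnight in [0, 24)

    def __post_init__(self):
        for name in ("n_neg", "n_pos", "n_cws", "n_irh", "n_probes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be a positive count")
        if self.tod is not None:
            tod = np.asarray(self.tod, dtype=float)
            if len(tod) != self.n_samples:
                raise ValueError("tod length must equal the total sample count")
            if np.any((tod < 0) | (tod >= 24)):
                raise ValueError("tod values must lie in [0, 24)")

    @property
    def n_samples(self) -> int:
        return self.n_neg + self.n_pos + self.n_cws + self.n_irh

    @property
    def n_genes(self) -> int:
        return -(-self.n_probes // self.probes_per_gene)


def default_design(n_probes: int = 18429, probes_per_gene: int = 2) -> StudyDesign:
    """The study layout this pipeline was built around: 7 HIV-negative
    controls, 10 lesion-free HIV-positive samples, 4 CWS and 6 IRH samples."""
    return StudyDesign(n_neg=7, n_pos=10, n_cws=4, n_irh=6,
                       n_probes=n_probes, probes_per_gene=probes_per_gene)


@dataclass
class PlantedTruth:
    """Ground truth of a generated study.

    ``planted_f`` maps each differentially expressed gene to its signed
    linear fold (|f| >= 1, positive = up in the HIV-positive groups).
    ``enriched_sets`` names gene sets constructed to be truly enriched;
    each must contain at least one planted gene.
    """

    de_genes: set = field(default_factory=set)
    planted_f: dict = field(default_factory=dict)
    enriched_sets: set = field(default_factory=set)

    def __post_init__(self):
        for g, f in self.planted_f.items():
            if -1.0 < f < 1.0:
                raise ValueError(f"planted fold for {g} in (-1, 1): {f}")


def draw_tod(n: int, rng: np.random.Generator,
             loc: float = 11.0, scale: float = 12.0) -> np.ndarray:
    """Times of death in hours, normal(loc, scale) truncated to [0, 24).

    The wide scale makes the truncated draw nearly uniform over the day:
    realized mean ~11.5 h and sd ~6.8 h, emulating autopsy cohorts whose
    deaths center on late morning with a ~7 h spread.  (No distribution
    supported on a 24 h day and unimodal can exceed the uniform sd of
    6.93 h, so ~6.8 h is as dispersed as this family gets.)
    """
    out = np.empty(n)
    got = 0
    while got < n:
        draw = rng.normal(loc, scale, size=2 * (n - got) + 8)
        draw = draw[(draw >= 0) & (draw < 24)]
        take = min(len(draw), n - got)
        out[got:got + take] = draw[:take]
        got += take
    return out


def _distort(x: np.ndarray, amp: float, degree: int) -> np.ndarray:
    """Monotone per-array distortion: x + amp * u**degree on a fixed domain."""
    if degree == 0 or amp == 0.0:
        return x
    u = np.clip((x - _DISTORT_LO) / (_DISTORT_HI - _DISTORT_LO), 0.0, 1.0)
    return x + amp * u ** degree


def generate_study(design: StudyDesign, noise_sd: float = 0.5,
                   distortion_degree: int = 3, seed: int = 0, *,
                   n_de_genes: int = 100, up_fold: tuple = (2.0, 5.0),
                   down_fold: tuple = (1.2, 1.4), frac_up: float = 0.7,
                   undetected_frac: float = 0.15):
    """Generate a log2 expression study with planted group differences.

    Returns ``(matrix, metadata, truth)`` where ``matrix`` is a probes x
    samples DataFrame of log2 values, ``metadata`` has one row per sample
    (sample, donor, group, lesion, tod) and ``truth`` records the planted
    genes and folds.

    The value of a probe in a sample is
    ``baseline + group_effect + per-array monotone distortion + noise``;
    planted effects (``sign(f) * log2|f|``) are added to every HIV-positive
    sample for all probes of a planted gene.  A fraction ``undetected_frac``
    of all probes sits at a low floor in every sample.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if distortion_degree < 0:
        raise ValueError("distortion_degree must be a small nonnegative integer")
    if not 0 <= undetected_frac < 1:
        raise ValueError("undetected_frac must be in [0, 1)")
    if design.n_samples < 1:
        raise ValueError("design has no samples")
    rng = np.random.default_rng(seed)

    # --- samples ------------------------------------------------------
    groups = (["neg"] * design.n_neg + ["pos"] * design.n_pos
              + ["cws"] * design.n_cws + ["irh"] * design.n_irh)
    lesions = (["none"] * (design.n_neg + design.n_pos)
               + ["CWS"] * design.n_cws + ["IRH"] * design.n_irh)
    counters = {}
    samples = []
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        samples.append(f"{g.upper()}{counters[g]:02d}")
    donors = [f"D{i + 1:02d}" for i in range(len(samples))]
    tod = (np.asarray(design.tod, dtype=float) if design.tod is not None
           else draw_tod(len(samples), rng))
    meta = pd.DataFrame({
        "sample": samples, "donor": donors, "group": groups,
        "lesion": lesions, "tod": np.round(tod, 3),
    }).set_index("sample")

    # --- probes and genes ---------------------------------------------
    gene_ids = [f"G{i:06d}" for i in range(design.n_genes)]
    probe_gene = np.repeat(gene_ids, design.probes_per_gene)[: design.n_probes]
    probe_ids = []
    seen = {}
    for g in probe_gene:
        seen[g] = seen.get(g, 0) + 1
        probe_ids.append(f"{g}_p{seen[g]}")

    baseline = np.clip(rng.normal(_EXPR_MEAN, _EXPR_SD, size=design.n_probes),
                       _EXPR_MIN, _EXPR_MAX)
    if design.n_probes > 1 and np.ptp(baseline) == 0:
        raise ValueError("degenerate constant baseline")

    # --- planted effects ----------------------------------------------
    n_de = min(n_de_genes, design.n_genes)
    de_genes = list(rng.choice(gene_ids, size=n_de, replace=False))
    n_up = int(round(frac_up * n_de))
    folds = np.concatenate([
        rng.uniform(up_fold[0], up_fold[1], size=n_up),
        -rng.uniform(down_fold[0], down_fold[1], size=n_de - n_up),
    ])
    planted_f = dict(zip(de_genes, folds))
    truth = PlantedTruth(de_genes=set(de_genes), planted_f=planted_f)

    delta = np.array([
        (np.sign(f) * np.log2(abs(f)) if (f := planted_f.get(g)) is not None else 0.0)
        for g in probe_gene
    ])
    is_positive = np.asarray([g != "neg" for g in groups])

    # --- assemble expressed block -------------------------------------
    values = baseline[:, None] + np.outer(delta, is_positive.astype(float))
    amps = (rng.uniform(-_DISTORT_AMP, _DISTORT_AMP, size=len(samples))
            if distortion_degree > 0 else np.zeros(len(samples)))
    for j in range(len(samples)):
        values[:, j] = _distort(values[:, j], amps[j], distortion_degree)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    # --- undetected floor block ---------------------------------------
    n_floor = int(round(design.n_probes * undetected_frac / (1.0 - undetected_frac)))
    if n_floor:
        floor_base = rng.normal(_FLOOR_MEAN, _FLOOR_SD, size=n_floor)
        floor_vals = np.tile(floor_base[:, None], (1, len(samples)))
        if noise_sd > 0:
            floor_vals = floor_vals + rng.normal(0.0, min(noise_sd, 0.3),
                                                 size=floor_vals.shape)
        floor_ids = [f"UND{i:06d}_p1" for i in range(n_floor)]
        values = np.vstack([values, floor_vals])
        probe_ids = probe_ids + floor_ids

    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=samples)
    return matrix, meta, truth


def probe_gene_map(probe_ids) -> pd.Series:
    """Probe -> gene mapping for generator-style probe ids (``GENE_pN``)."""
    return pd.Series({p: p.rsplit("_p", 1)[0] for p in probe_ids}, name="gene_id")


def generate_geneset_collection(universe, n_sets: int, size_range: tuple,
                                overlap_rate: float, seed: int = 0) -> GeneSetCollection:
    """Random gene sets over ``universe`` with controllable pairwise overlap.

    Each set draws ``round(overlap_rate * size)`` members from a shared core
    pool (of the maximum set size) and the rest uniformly from the remaining
    universe; ``overlap_rate=0`` gives independent chance-level overlaps,
    ``overlap_rate=1`` with equal sizes gives identical sets.
    """
    universe = list(universe)
    lo, hi = size_range
    if lo > hi:
        raise ValueError(f"size_range inverted: {size_range}")
    if lo < 1:
        raise ValueError("minimum set size must be >= 1")
    if hi > len(universe):
        raise ValueError("max set size exceeds the universe")
    if not 0 <= overlap_rate <= 1:
        raise ValueError("overlap_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    uni = np.asarray(universe, dtype=object)
    core_idx = rng.choice(len(uni), size=hi, replace=False)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        n_core = int(round(overlap_rate * size))
        members = core_idx[:n_core]
        rest = np.setdiff1d(np.arange(len(uni)), members, assume_unique=False)
        extra = rng.choice(rest, size=size - n_core, replace=False)
        sets[f"SET{i:03d}"] = list(uni[np.concatenate([members, extra])])
    return GeneSetCollection(sets, {n: "synthetic" for n in sets})


def with_set(collection: GeneSetCollection, name: str, members) -> GeneSetCollection:
    """Return a copy of ``collection`` with one extra (e.g. planted) set."""
    sets = {n: m for n, m in collection.items()}
    desc = {n: collection.description(n) for n in collection.names}
    if name in sets:
        raise ValueError(f"set {name!r} already present")
    sets[name] = members
    desc[name] = "planted"
    return GeneSetCollection(sets, desc)


# Default qPCR panel: rod opsin up ~4.4-fold, blue cone opsin mildly down,
# a crystallin mildly up, all relative to the GAPDH reference.
_QPCR_FOLDS = {"RHO": 4.4, "OPN1SW": -1.4, "CRYBB2": 1.8}
_QPCR_BASELINE = {"RHO": 2.0, "OPN1SW": -4.0, "CRYBB2": -2.0}


def generate_qpcr(design: StudyDesign, amplitude: float = 0.0,
                  phase: float = 6.0, seed: int = 0, *,
                  noise_sd: float = 0.3, reference: str = "GAPDH",
                  folds: dict | None = None) -> pd.DataFrame:
    """Per-sample Ct values for a target panel plus the reference gene.

    Log2 abundance relative to the reference is
    ``baseline + group effect + amplitude * cos(2*pi*(tod - phase)/24) + noise``;
    Ct_target = Ct_reference - log2 abundance.  ``amplitude`` (log2 units)
    and ``phase`` (peak hour) inject a diurnal rhythm; amplitude 0 makes
    abundance independent of time of death up to noise.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    folds = dict(_QPCR_FOLDS if folds is None else folds)
    rng = np.random.default_rng(seed)
    groups = (["neg"] * design.n_neg + ["pos"] * design.n_pos
              + ["cws"] * design.n_cws + ["irh"] * design.n_irh)
    counters, samples = {}, []
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        samples.append(f"{g.upper()}{counters[g]:02d}")
    tod = (np.asarray(design.tod, dtype=float) if design.tod is not None
           else draw_tod(len(samples), rng))

    rows = []
    for s, g, t in zip(samples, groups, tod):
        ct_ref = 20.0 + rng.normal(0.0, 0.1)
        rows.append({"sample": s, "gene": reference, "Ct": ct_ref,
                     "tod": round(float(t), 3), "group": g})
        for gene, f in folds.items():
            la = _QPCR_BASELINE.get(gene, 0.0)
            if g != "neg":
                la += np.sign(f) * np.log2(abs(f))
            la += amplitude * np.cos(2 * np.pi * (t - phase) / 24.0)
            if noise_sd > 0:
                la += rng.normal(0.0, noise_sd)
            rows.append({"sample": s, "gene": gene, "Ct": ct_ref - la,
                         "tod": round(float(t), 3), "group": g})
    return pd.DataFrame(rows)
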