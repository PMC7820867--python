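"""Synthetic paired tumor/healthy study generator.

Emulates the study design that motivates this package: ~40 patients each
contributing a tumor and an adjacent healthy-mucosa sample, a Luminex-style
cytokine panel (right-skewed, censored at assay quantification limits), and
16S genus-level counts whose composition responds to cytokine levels through
a sparse log-link Dirichlet-multinomial model. Because the generative model
mirrors the inference model, coefficient recovery is well-posed and every
downstream stage can be tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import apply_loq, standardize_covariates
from .tables import (
    RANKS,
    CompositionResponse,
    CytokinePanel,
    LoqTable,
    OtuTable,
    SamplePairing,
)

__all__ = [
    "GroundTruth",
    "StudyConfig",
    "SyntheticStudy",
    "default_loq",
    "generate_cytokine_panel",
    "generate_dm_counts",
    "generate_paired_study",
]

#: Genus names used for the J-1 focal response categories (J = 4 default
#: mirrors the three dominant colorectal mucosa genera plus the residual).
FOCAL_GENERA = ("Bacteroides", "Prevotella", "Escherichia/Shigella")

BACKGROUND_GENERA = (
    "Faecalibacterium", "Ruminococcus", "Roseburia", "Blautia", "Alistipes",
    "Akkermansia", "Fusobacterium", "Parabacteroides", "Dorea", "Coprococcus",
    "Oscillibacter", "Streptococcus", "Veillonella", "Sutterella", "Bilophila",
    "Odoribacter", "Butyricimonas", "Anaerostipes", "Collinsella", "Dialister",
    "Eubacterium", "Holdemania", "Lachnospira", "Megasphaera", "Paraprevotella",
    "Phascolarctobacterium", "Slackia", "Subdoligranulum", "Turicibacter",
    "Victivallis",
)


@dataclass
class GroundTruth:
    """True regression coefficients behind a synthetic study.

    ``coefficient_matrix`` is (K+1) x J on the log-link scale, row 0 the
    intercepts; entries outside ``active_set`` (excluding the intercept row)
    are exactly zero. ``overdispersion`` is the total Dirichlet concentration
    scale: with an all-zero coefficient matrix each sample's concentrations
    sum to exactly this value.
    """

    coefficient_matrix: np.ndarray
    active_set: frozenset[tuple[int, int]]
    overdispersion: float
    seed: int

    def __post_init__(self) -> None:
        self.coefficient_matrix = np.asarray(self.coefficient_matrix, dtype=float)
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        K1, J = self.coefficient_matrix.shape
        for k in range(1, K1):
            for j in range(J):
                if (k, j) not in self.active_set and self.coefficient_matrix[k, j] != 0:
                    raise ValueError(
                        f"coefficient ({k},{j}) nonzero but outside the active set"
                    )


@dataclass
class StudyConfig:
    """Knobs of the synthetic study. Defaults match the emulated design:
    40 sequenced patient pairs, 8 candidate cytokines, a 4-category response,
    2 truly active cytokine-category pairs of log-link magnitude 1.5, and
    sequencing depths uniform on [1e4, 1e5]."""

    n_patients: int = 40
    n_cytokines: int = 8
    n_categories: int = 4
    n_active: int = 2
    effect_size: float = 1.5
    depth_range: tuple[int, int] = (10_000, 100_000)
    overdispersion: float = 50.0
    log_sd: float = 1.0
    tissue_shift: float = 0.5
    patient_effect_sd: float = 0.3
    n_background_genera: int = 20
    seed: int = 0
    cytokine_names: list[str] | None = None

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_cytokines < 1:
            raise ValueError("n_cytokines must be >= 1")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        if self.n_active > self.n_cytokines * self.n_categories:
            raise ValueError("n_active exceeds the number of coefficient slots")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ValueError("invalid depth_range")


@dataclass
class SyntheticStudy:
    """A complete simulated study with its generating truth."""

    cytokine_panel: CytokinePanel
    composition: CompositionResponse
    otu_table: OtuTable
    pairing: SamplePairing
    truth: GroundTruth
    config: StudyConfig = field(repr=False, default_factory=StudyConfig)


def default_loq(cytokine_names: list[str]) -> LoqTable:
    """Fallback quantification limits for made-up cytokine names."""
    return LoqTable(
        {c: 2.0 for c in cytokine_names}, {c: 10_000.0 for c in cytokine_names}
    )


def generate_cytokine_panel(
    n_patients: int,
    cytokine_names: list[str],
    tissue_shift: np.ndarray | float,
    loq: LoqTable,
    seed: int,
    log_sd: float = 1.0,
) -> CytokinePanel:
    """Draw a paired-design Luminex-style panel (2 samples per patient).

    Per-cytokine values are log-normal with the log-median anchored at four
    times the cytokine's LLOQ (so a realistic fraction of values falls below
    the limit and exercises the censoring path); tumor samples are shifted by
    ``tissue_shift`` on the log scale. Censoring is *not* applied here — that
    is the preprocessing stage's job.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if len(set(cytokine_names)) != len(cytokine_names):
        raise ValueError("duplicate cytokine names")
    missing = [c for c in cytokine_names if c not in loq]
    if missing:
        raise ValueError(f"no quantification limits for: {missing}")
    K = len(cytokine_names)
    shift = np.broadcast_to(np.asarray(tissue_shift, dtype=float), (K,))
    rng = np.random.default_rng(seed)
    log_median = np.log([4.0 * loq.lloq[c] for c in cytokine_names])
    z = rng.normal(size=(2 * n_patients, K))
    logv = log_median[None, :] + log_sd * z
    sample_ids = []
    for p in range(n_patients):
        sample_ids += [f"P{p + 1:03d}_T", f"P{p + 1:03d}_H"]
    tumor_rows = np.arange(0, 2 * n_patients, 2)
    logv[tumor_rows] += shift[None, :]
    return CytokinePanel(np.exp(logv), sample_ids, list(cytokine_names))


def generate_dm_counts(
    design: np.ndarray,
    truth: GroundTruth,
    depths: np.ndarray,
    seed: int,
    log_alpha_offset: np.ndarray | None = None,
) -> CompositionResponse:
    """Draw Dirichlet-multinomial counts from the log-link model.

    For sample i, alpha_i = (s/J) * exp(design_i @ B) with s the truth's
    overdispersion (so a zero coefficient matrix yields total concentration
    exactly s); p_i ~ Dirichlet(alpha_i); counts_i ~ Multinomial(depths[i],
    p_i). ``log_alpha_offset`` (n x J) adds sample-level log-concentration
    shifts, used for patient random effects.
    """
    X = np.asarray(design, dtype=float)
    depths = np.asarray(depths)
    B = truth.coefficient_matrix
    if X.ndim != 2 or X.shape[1] != B.shape[0]:
        raise ValueError("design columns must match coefficient matrix rows")
    if depths.shape != (X.shape[0],) or (depths < 1).any():
        raise ValueError("depths must be positive integers, one per sample")
    J = B.shape[1]
    eta = X @ B + np.log(truth.overdispersion / J)
    if log_alpha_offset is not None:
        eta = eta + np.asarray(log_alpha_offset, dtype=float)
    alpha = np.exp(eta)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("non-finite concentration parameters")
    rng = np.random.default_rng(seed)
    counts = np.empty((X.shape[0], J), dtype=np.int64)
    for i in range(X.shape[0]):
        p = rng.dirichlet(alpha[i])
        counts[i] = rng.multinomial(int(depths[i]), p)
    sample_ids = [f"S{i + 1:04d}" for i in range(X.shape[0])]
    names = list(FOCAL_GENERA[: J - 1]) if J - 1 <= len(FOCAL_GENERA) else [
        f"Genus_{j + 1}" for j in range(J - 1)
    ]
    return CompositionResponse(counts, sample_ids, names + ["residual"])


def _make_truth(config: StudyConfig, rng: np.random.Generator) -> GroundTruth:
    K, J = config.n_cytokines, config.n_categories
    B = np.zeros((K + 1, J))
    # graded focal intercepts with a dominant residual, as in real mucosa
    # tables where the pooled tail holds ~40-50% of reads
    B[0, : J - 1] = np.linspace(0.5, 0.2, J - 1)
    B[0, -1] = 1.2
    slots = [(k, j) for k in range(1, K + 1) for j in range(J)]
    chosen = rng.choice(len(slots), size=config.n_active, replace=False)
    active = set()
    for c in chosen:
        k, j = slots[c]
        B[k, j] = config.effect_size * rng.choice([-1.0, 1.0])
        active.add((k, j))
    return GroundTruth(B, frozenset(active), config.overdispersion, config.seed)


def _expand_to_otus(
    composition: CompositionResponse,
    sample_ids: list[str],
    n_background: int,
    rng: np.random.Generator,
) -> OtuTable:
    """Split the residual category across background genera and each genus
    across a few OTUs, producing a realistic sparse OTU table whose
    genus-level aggregation partitions the composition counts exactly."""
    J = composition.n_categories
    focal = composition.category_names[: J - 1]
    background = list(BACKGROUND_GENERA[:n_background])
    if n_background > len(BACKGROUND_GENERA):
        background += [f"Genus_{k}" for k in range(len(BACKGROUND_GENERA), n_background)]
    # fixed long-tail abundance profile for the residual split; the spread is
    # kept moderate so no single background genus rivals the focal genera
    bg_weights = rng.lognormal(mean=0.0, sigma=0.6, size=n_background)
    bg_weights /= bg_weights.sum()
    genus_names = focal + background
    otu_ids: list[str] = []
    otu_genus: list[int] = []
    otu_weights: list[np.ndarray] = []
    for g_idx, _ in enumerate(genus_names):
        n_otus = int(rng.integers(1, 6))
        w = rng.dirichlet(np.full(n_otus, 0.7))
        for _ in range(n_otus):
            otu_ids.append(f"OTU_{len(otu_ids) + 1:04d}")
            otu_genus.append(g_idx)
        otu_weights.append(w)
    counts = np.zeros((len(sample_ids), len(otu_ids)), dtype=np.int64)
    col = 0
    genus_counts = np.zeros((len(sample_ids), len(genus_names)), dtype=np.int64)
    genus_counts[:, : J - 1] = composition.counts[:, : J - 1]
    for i in range(len(sample_ids)):
        genus_counts[i, J - 1 :] = rng.multinomial(
            int(composition.counts[i, -1]), bg_weights
        )
    col = 0
    for g_idx in range(len(genus_names)):
        w = otu_weights[g_idx]
        for i in range(len(sample_ids)):
            counts[i, col : col + w.size] = rng.multinomial(
                int(genus_counts[i, g_idx]), w
            )
        col += w.size
    taxonomy = {}
    for otu, g_idx in zip(otu_ids, otu_genus):
        genus = genus_names[g_idx]
        lineage = ["Bacteria_phylum", "Bacteria_class", "Bacteria_order", "Bacteria_family", genus]
        taxonomy[otu] = tuple(lineage[-len(RANKS) :])
    return OtuTable(counts, list(sample_ids), otu_ids, taxonomy)


def generate_paired_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Assemble a full synthetic paired study from a config.

    The cytokine panel is generated, censored at default limits and
    standardized exactly as the analysis pipeline would, and the resulting
    design matrix drives the Dirichlet-multinomial counts — so the recorded
    ground-truth coefficients are the ones the two-step analysis should
    recover. A per-patient random effect on the log concentrations (shared by
    the patient's two samples) makes paired samples more similar to each
    other than to other patients'.
    """
    config = config or StudyConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.cytokine_names or [f"CYT{k + 1:02d}" for k in range(config.n_cytokines)]
    if len(names) != config.n_cytokines:
        raise ValueError("cytokine_names length must equal n_cytokines")
    loq = default_loq(names)
    panel = generate_cytokine_panel(
        config.n_patients,
        names,
        config.tissue_shift,
        loq,
        seed=int(rng.integers(2**31)),
        log_sd=config.log_sd,
    )
    censored = apply_loq(panel, loq)
    design = standardize_covariates(censored)
    truth = _make_truth(config, rng)
    n = 2 * config.n_patients
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n)
    patient_effect = rng.normal(
        scale=config.patient_effect_sd, size=(config.n_patients, config.n_categories)
    )
    offset = np.repeat(patient_effect, 2, axis=0)
    composition = generate_dm_counts(
        design.X, truth, depths, seed=int(rng.integers(2**31)), log_alpha_offset=offset
    )
    composition = CompositionResponse(
        composition.counts, list(panel.sample_ids), composition.category_names
    )
    otu_table = _expand_to_otus(
        composition, list(panel.sample_ids), config.n_background_genera, rng
    )
    pairing = SamplePairing(
        {
            f"P{p + 1:03d}": (f"P{p + 1:03d}_T", f"P{p + 1:03d}_H")
            for p in range(config.n_patients)
        }
    )
    return SyntheticStudy(panel, composition, otu_table, pairing, truth, config)
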