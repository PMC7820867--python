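"""Tabular containers and readers/writers for the analysis inputs.

All on-disk formats are plain text: counts, taxonomy and pairing tables are
tab-separated (UTF-8, header row mandatory, samples in rows unless
``transpose`` is requested); cytokine panels and quantification-limit tables
are comma-separated. Writers emit the same dialects the readers accept, so
every table round-trips bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered taxonomic ranks carried by a taxonomy table (domain level is
#: upstream's concern; genus is the finest rank 16S classification supports).
RANKS = ("phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"


class TableError(ValueError):
    """Malformed or inconsistent input table."""


@dataclass
class OtuTable:
    """Samples x taxa count matrix with a ranked taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per sample.
    sample_ids, taxon_ids
        Unique row / column labels.
    taxonomy
        Mapping ``taxon_id -> tuple of rank labels`` ordered as :data:`RANKS`.
        Entries may be ``"unclassified"``.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    taxonomy: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableError("counts must be a 2-D matrix")
        if self.counts.size == 0:
            raise TableError("empty count table")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise TableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if len(self.sample_ids) != self.counts.shape[0]:
            raise TableError("sample_ids length does not match counts rows")
        if len(self.taxon_ids) != self.counts.shape[1]:
            raise TableError("taxon_ids length does not match counts columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise TableError("duplicate taxon ids")
        missing = [t for t in self.taxon_ids if t not in self.taxonomy]
        if self.taxonomy or missing == self.taxon_ids:
            for t in missing:
                self.taxonomy[t] = (UNCLASSIFIED,) * len(RANKS)
            if missing and len(missing) < len(self.taxon_ids):
                logger.warning(
                    "%d taxa missing from taxonomy; lineage set to 'unclassified': %s",
                    len(missing), ", ".join(missing[:5]),
                )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        """Row-subset preserving the requested order."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            self.counts[idx], list(sample_ids), list(self.taxon_ids), dict(self.taxonomy)
        )


@dataclass
class CytokinePanel:
    """Samples x cytokines concentrations in pg/ml.

    ``censored_mask`` is True where a value was set to 0 by the
    lower-limit-of-quantification rule; ``uloq_mask`` flags values at or above
    the upper limit.
    """

    values: np.ndarray
    sample_ids: list[str]
    cytokine_names: list[str]
    censored_mask: np.ndarray | None = None
    uloq_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableError("values must be 2-D")
        if len(set(self.cytokine_names)) != len(self.cytokine_names):
            raise TableError("duplicate cytokine names")
        if len(self.sample_ids) != self.values.shape[0]:
            raise TableError("sample_ids length mismatch")
        if len(self.cytokine_names) != self.values.shape[1]:
            raise TableError("cytokine_names length mismatch")
        if self.censored_mask is None:
            self.censored_mask = np.zeros_like(self.values, dtype=bool)
        if self.uloq_mask is None:
            self.uloq_mask = np.zeros_like(self.values, dtype=bool)
        for name, mask in (("censored_mask", self.censored_mask),
                           ("uloq_mask", self.uloq_mask)):
            if np.asarray(mask).shape != self.values.shape:
                raise TableError(f"{name} shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.cytokine_names
        )

    def select_samples(self, sample_ids: list[str]) -> "CytokinePanel":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CytokinePanel(
            self.values[idx], list(sample_ids), list(self.cytokine_names),
            self.censored_mask[idx], self.uloq_mask[idx],
        )

    def select_cytokines(self, names: list[str]) -> "CytokinePanel":
        idx = [self.cytokine_names.index(c) for c in names]
        return CytokinePanel(
            self.values[:, idx], list(self.sample_ids), list(names),
            self.censored_mask[:, idx], self.uloq_mask[:, idx],
        )


@dataclass
class LoqTable:
    """Per-cytokine lower/upper limits of quantification (pg/ml)."""

    lloq: dict[str, float]
    uloq: dict[str, float]

    def __post_init__(self) -> None:
        for c, lo in self.lloq.items():
            hi = self.uloq.get(c)
            if hi is None:
                raise TableError(f"cytokine {c!r} has LLOQ but no ULOQ")
            if not (0 < lo < hi):
                raise TableError(f"cytokine {c!r}: require 0 < LLOQ < ULOQ, got {lo}, {hi}")

    def __contains__(self, cytokine: str) -> bool:
        return cytokine in self.lloq


@dataclass
class SamplePairing:
    """patient_id -> (tumor_sample_id, healthy_sample_id)."""

    pairs: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, (t, h) in self.pairs.items():
            if t == h:
                raise TableError(f"patient {pid!r}: tumor and healthy sample ids coincide")
            for s in (t, h):
                if s in seen:
                    raise TableError(f"sample id {s!r} appears in more than one pair")
                seen.add(s)

    @property
    def patients(self) -> list[str]:
        return list(self.pairs)

    def tumor_samples(self) -> list[str]:
        return [t for t, _ in self.pairs.values()]

    def healthy_samples(self) -> list[str]:
        return [h for _, h in self.pairs.values()]

    def samples_for_tissue(self, tissue: str) -> list[str]:
        if tissue == "tumor":
            return self.tumor_samples()
        if tissue == "healthy":
            return self.healthy_samples()
        raise ValueError(f"unknown tissue {tissue!r} (expected 'tumor' or 'healthy')")


@dataclass
class CompositionResponse:
    """Samples x J category counts: the top genera plus a residual category.

    The last category is always the residual; per-sample totals equal the
    totals of the source table (counts are partitioned, never dropped).
    """

    counts: np.ndarray
    sample_ids: list[str]
    category_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise TableError("negative category counts")
        if self.counts.shape != (len(self.sample_ids), len(self.category_names)):
            raise TableError("shape / label mismatch")

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.category_names
        )

    def select_samples(self, sample_ids: list[str]) -> "CompositionResponse":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CompositionResponse(
            self.counts[idx], list(sample_ids), list(self.category_names)
        )


@dataclass
class DesignMatrix:
    """Regression design: intercept column of ones plus standardized covariates."""

    X: np.ndarray
    sample_ids: list[str]
    covariate_names: list[str]
    transform_record: str = "none"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.sample_ids), len(self.covariate_names) + 1):
            raise TableError("design shape mismatch (intercept column expected)")
        if not np.allclose(self.X[:, 0], 1.0):
            raise TableError("first design column must be the intercept of ones")

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)


# ---------------------------------------------------------------------------
# Readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str, encoding="utf-8")


def read_otu_table(
    counts_path: str | Path,
    taxonomy_path: str | Path | None = None,
    transpose: bool = False,
) -> OtuTable:
    """Load a counts TSV (samples in rows) and an optional taxonomy TSV.

    Taxa present in the counts but absent from the taxonomy get an
    all-"unclassified" lineage and a logged warning. Set ``transpose`` for
    taxa-in-rows dialects.
    """
    df = _read_tsv(counts_path)
    if df.empty:
        raise TableError(f"empty count table: {counts_path}")
    if transpose:
        df = df.T
    try:
        values = df.to_numpy(dtype=np.int64)
    except (TypeError, ValueError):
        for i, row in enumerate(df.itertuples(index=False)):
            for j, v in enumerate(row):
                try:
                    iv = int(v)
                except (TypeError, ValueError):
                    raise TableError(
                        f"non-integer count {v!r} at sample {df.index[i]!r}, "
                        f"taxon {df.columns[j]!r}"
                    ) from None
                if iv < 0:
                    raise TableError(
                        f"negative count {iv} at sample {df.index[i]!r}, "
                        f"taxon {df.columns[j]!r}"
                    )
        raise
    taxonomy: dict[str, tuple[str, ...]] = {}
    if taxonomy_path is not None:
        tdf = _read_tsv(taxonomy_path)
        rank_cols = [c for c in tdf.columns if c.lower() in RANKS]
        if not rank_cols:
            raise TableError(f"taxonomy file {taxonomy_path} has no rank columns")
        for taxon, row in tdf.iterrows():
            taxonomy[str(taxon)] = tuple(
                str(row[c]) if pd.notna(row[c]) else UNCLASSIFIED for c in rank_cols
            )
    return OtuTable(values, [str(s) for s in df.index], [str(t) for t in df.columns], taxonomy)


def write_otu_table(
    table: OtuTable, counts_path: str | Path, taxonomy_path: str | Path | None = None
) -> None:
    table.to_frame().to_csv(counts_path, sep="\t", index_label="sample_id", encoding="utf-8")
    if taxonomy_path is not None:
        rows = {t: table.taxonomy[t] for t in table.taxon_ids}
        n_ranks = max((len(v) for v in rows.values()), default=len(RANKS))
        tdf = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)[:n_ranks])
        tdf.to_csv(taxonomy_path, sep="\t", index_label="taxon_id", encoding="utf-8")


def read_cytokine_panel(path: str | Path) -> CytokinePanel:
    """Load a samples x cytokines CSV (pg/ml)."""
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    if df.empty:
        raise TableError(f"empty cytokine panel: {path}")
    return CytokinePanel(
        df.to_numpy(dtype=float),
        [str(s) for s in df.index],
        [str(c) for c in df.columns],
    )


def write_cytokine_panel(panel: CytokinePanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index_label="sample_id", encoding="utf-8")


def read_loq_table(path: str | Path) -> LoqTable:
    df = pd.read_csv(path, encoding="utf-8")
    df.columns = [c.strip().lower() for c in df.columns]
    # decimal commas (assay-sheet dialect) are normalized to points
    def _num(x: object) -> float:
        return float(str(x).replace(",", "."))

    lloq = {str(r["cytokine"]): _num(r["lloq_pg_ml"]) for _, r in df.iterrows()}
    uloq = {str(r["cytokine"]): _num(r["uloq_pg_ml"]) for _, r in df.iterrows()}
    return LoqTable(lloq, uloq)


def packaged_loq_table() -> LoqTable:
    """The 26-cytokine Luminex panel limits shipped with the package."""
    with resources.as_file(resources.files("cytodm.data") / "loq_table.csv") as p:
        return read_loq_table(p)


def packaged_data_path(name: str) -> Path:
    """Path to a small packaged example table (copied out for file-based APIs)."""
    with resources.as_file(resources.files("cytodm.data") / name) as p:
        return Path(p)


def read_pairing(path: str | Path) -> SamplePairing:
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    required = {"patient_id", "tumor_sample_id", "healthy_sample_id"}
    if not required.issubset(df.columns):
        raise TableError(f"pairing table must have columns {sorted(required)}")
    return SamplePairing(
        {
            str(r.patient_id): (str(r.tumor_sample_id), str(r.healthy_sample_id))
            for r in df.itertuples()
        }
    )


def write_pairing(pairing: SamplePairing, path: str | Path) -> None:
    pd.DataFrame(
        [(p, t, h) for p, (t, h) in pairing.pairs.items()],
        columns=["patient_id", "tumor_sample_id", "healthy_sample_id"],
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")
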