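"""Count-table data model and I/O for pooled barcode fitness assays.

A dataset is a variants x samples integer count table plus a sample design:
each sample belongs to one assay (one batch-culture competition) and carries a
real-valued timepoint. Counts are depth-normalized and log-transformed before
any fitting; the pseudocount keeps log-counts finite at zero counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssayDesign",
    "CountDataset",
    "LogCountMatrix",
    "read_counts",
    "write_counts",
    "read_control_set",
    "normalize_depth",
    "assay_column_slices",
]


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass(frozen=True)
class AssayDesign:
    """One assay: ordered timepoints and the sample id observed at each.

    At least three timepoints are required so that a line fit leaves at least
    one residual degree of freedom.
    """

    assay_id: str
    timepoints: tuple[float, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay_id", str(self.assay_id))
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if len(self.timepoints) != len(self.sample_ids):
            raise ValueError(
                f"assay {self.assay_id!r}: {len(self.timepoints)} timepoints but "
                f"{len(self.sample_ids)} sample ids"
            )
        if len(self.timepoints) < 3:
            raise ValueError(
                f"assay {self.assay_id!r} has {len(self.timepoints)} timepoints; "
                "at least 3 are required (line fit plus a residual degree of freedom)"
            )
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError(
                f"assay {self.assay_id!r}: timepoints must be strictly increasing, "
                f"got {self.timepoints}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"assay {self.assay_id!r}: duplicate sample ids")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def times(self) -> np.ndarray:
        return np.asarray(self.timepoints, dtype=float)


def assay_column_slices(assays) -> list[tuple["AssayDesign", np.ndarray]]:
    """Column index arrays, one per assay, in dataset column order."""
    out = []
    start = 0
    for assay in assays:
        idx = np.arange(start, start + assay.n_timepoints)
        out.append((assay, idx))
        start += assay.n_timepoints
    return out


@dataclass(frozen=True)
class CountDataset:
    """Barcode read counts over variants x samples with assay/timepoint design.

    Columns are ordered assay by assay, timepoints ascending within an assay.
    ``depths`` holds the per-sample sequencing depth used for normalization
    (by default the column sum; may be supplied externally, e.g. spike-ins).
    """

    variant_ids: tuple[str, ...]
    assays: tuple[AssayDesign, ...]
    counts: np.ndarray
    depths: np.ndarray
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_ids", tuple(str(v) for v in self.variant_ids))
        object.__setattr__(self, "assays", tuple(self.assays))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D (variants x samples) array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        depths = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "depths", depths)

        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")
        sample_ids = self.sample_ids
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids across assays")
        n_samples = len(sample_ids)
        if counts.shape != (len(self.variant_ids), n_samples):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.variant_ids)} variants x {n_samples} samples"
            )
        if depths.shape != (n_samples,):
            raise ValueError("depths must hold one value per sample")
        if not np.all(np.isfinite(depths)) or np.any(depths <= 0):
            raise ValueError("depths must be positive and finite")
        if not (np.isfinite(self.pseudocount) and self.pseudocount >= 0):
            raise ValueError("pseudocount must be a nonnegative real")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s for assay in self.assays for s in assay.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def assay_slices(self) -> list[tuple[AssayDesign, np.ndarray]]:
        return assay_column_slices(self.assays)

    def all_zero_mask(self) -> np.ndarray:
        """Boolean (variants x assays): True where an assay has only zero counts."""
        cols = [idx for _, idx in self.assay_slices()]
        return np.column_stack([(self.counts[:, idx] == 0).all(axis=1) for idx in cols])

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for assay, idx in self.assay_slices():
            for j, (s, t) in enumerate(zip(assay.sample_ids, assay.timepoints)):
                rows.append(
                    {
                        "sample_id": s,
                        "assay_id": assay.assay_id,
                        "timepoint": t,
                        "depth": self.depths[idx[j]],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LogCountMatrix:
    """Depth-normalized (or bias-corrected) log-counts with the assay design.

    ``observed`` flags variant-assay blocks that carried at least one nonzero
    count; all-zero blocks are excluded from fits rather than dropped globally.
    """

    variant_ids: tuple[str, ...]
    assays: tuple[AssayDesign, ...]
    values: np.ndarray
    provenance: str = "raw"
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_ids", tuple(str(v) for v in self.variant_ids))
        object.__setattr__(self, "assays", tuple(self.assays))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.provenance not in ("raw", "normalized", "corrected"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        n_samples = sum(a.n_timepoints for a in self.assays)
        if values.shape != (len(self.variant_ids), n_samples):
            raise ValueError("log-count matrix shape does not match design")
        if not np.all(np.isfinite(values)):
            raise ValueError(
                "log-counts must be finite; use a positive pseudocount for zero counts"
            )
        if self.observed is not None:
            obs = np.asarray(self.observed, dtype=bool)
            if obs.shape != (len(self.variant_ids), len(self.assays)):
                raise ValueError("observed mask must be variants x assays")
            object.__setattr__(self, "observed", obs)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s for assay in self.assays for s in assay.sample_ids)

    def assay_slices(self) -> list[tuple[AssayDesign, np.ndarray]]:
        return assay_column_slices(self.assays)

    def replace_values(self, values: np.ndarray, provenance: str) -> "LogCountMatrix":
        return LogCountMatrix(
            self.variant_ids, self.assays, values, provenance, self.observed
        )


def read_counts(counts_path, metadata_path, pseudocount: float = 0.5) -> CountDataset:
    """Read a delimited count table and sample metadata into a CountDataset.

    The count table has a header of sample ids and variant ids in the first
    column. Metadata maps ``sample_id`` to ``assay_id`` and ``timepoint``; an
    optional ``depth`` column overrides column-sum depths (e.g. spike-in
    normalization). Delimiter is comma for ``.csv`` files, tab otherwise.
    """
    counts_df = pd.read_csv(counts_path, sep=_sep_for(counts_path), index_col=0)
    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path))
    required = {"sample_id", "assay_id", "timepoint"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata is missing columns: {sorted(missing_cols)}")
    meta = meta.assign(sample_id=meta["sample_id"].astype(str)).set_index("sample_id")
    if meta.index.duplicated().any():
        dups = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample_id rows in metadata: {dups}")

    sample_cols = [str(c) for c in counts_df.columns]
    counts_df.columns = sample_cols
    for col in sample_cols:
        if col not in meta.index:
            raise ValueError(f"sample column {col!r} has no metadata row")

    raw = counts_df.to_numpy()
    if not np.all(np.isfinite(raw.astype(float))) or np.any(raw.astype(float) != np.round(raw.astype(float))):
        raise ValueError("counts must be finite integers")
    if np.any(raw.astype(float) < 0):
        raise ValueError("counts must be nonnegative")

    sub = meta.loc[sample_cols]
    assays = []
    ordered_samples: list[str] = []
    for assay_id in dict.fromkeys(sub["assay_id"]):
        rows = sub[sub["assay_id"] == assay_id].sort_values("timepoint")
        assays.append(
            AssayDesign(
                assay_id=str(assay_id),
                timepoints=tuple(rows["timepoint"].astype(float)),
                sample_ids=tuple(rows.index),
            )
        )
        ordered_samples.extend(rows.index)

    counts = counts_df[ordered_samples].to_numpy().astype(np.int64)
    if "depth" in sub.columns and sub["depth"].notna().any():
        if sub["depth"].isna().any():
            bad = sub.index[sub["depth"].isna()].tolist()
            raise ValueError(f"metadata depth column is partially specified; missing for {bad}")
        depths = sub.loc[ordered_samples, "depth"].to_numpy(dtype=float)
    else:
        depths = counts.sum(axis=0).astype(float)
        zero = np.flatnonzero(depths == 0)
        if zero.size:
            bad = [ordered_samples[j] for j in zero]
            raise ValueError(f"zero total depth in sample(s) {bad}")

    return CountDataset(
        variant_ids=tuple(str(v) for v in counts_df.index),
        assays=tuple(assays),
        counts=counts,
        depths=depths,
        pseudocount=pseudocount,
    )


def write_counts(dataset: CountDataset, counts_path, metadata_path) -> None:
    """Write a dataset back to a count table and metadata table (round-trips)."""
    counts_df = pd.DataFrame(
        dataset.counts, index=list(dataset.variant_ids), columns=list(dataset.sample_ids)
    )
    counts_df.index.name = "variant_id"
    counts_df.to_csv(counts_path, sep=_sep_for(counts_path))
    dataset.sample_table().to_csv(metadata_path, sep=_sep_for(metadata_path), index=False)


def read_control_set(path) -> tuple[str, ...]:
    """Read the equal-fitness control set: one variant id per line ('#' comments)."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    if not ids:
        raise ValueError(f"control set file {path} contains no variant ids")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in control set")
    return tuple(ids)


def normalize_depth(dataset: CountDataset) -> LogCountMatrix:
    """Depth-normalize counts onto a common scale and take natural logs.

    logC[i, s] = log((C[i, s] + pseudocount) / depth_s * Dbar) with Dbar the
    geometric mean depth, so equal-depth data reduces to log(C + pseudocount).
    """
    depths = dataset.depths
    gmean = float(np.exp(np.mean(np.log(depths))))
    with np.errstate(divide="ignore"):
        values = np.log((dataset.counts + dataset.pseudocount) / depths * gmean)
    if not np.all(np.isfinite(values)):
        raise ValueError("zero counts with pseudocount 0 produce -inf log-counts")
    observed = ~dataset.all_zero_mask()
    n_excluded = int((~observed).sum())
    if n_excluded:
        logger.info(
            "%d variant-assay blocks have all-zero counts and are excluded from fits",
            n_excluded,
        )
    return LogCountMatrix(
        variant_ids=dataset.variant_ids,
        assays=dataset.assays,
        values=values,
        provenance="normalized",
        observed=observed,
    )
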