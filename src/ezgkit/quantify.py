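"""Count-matrix container, normalization and TSV input/output.

Expression values are normalized per transcript length and per library
size: reads per kilobase per million mapped reads. Library sizes are the
total mapped hit counts per time bin; for a subset matrix they must be
supplied explicitly, otherwise the column sums of the matrix are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Embryonic time bins, in order.
BIN_LABELS = ("0-2", "2-4", "4-8", "8-12")

#: Column names used for the four bins in counts TSV files.
BIN_COLUMNS = ("h0_2", "h2_4", "h4_8", "h8_12")

N_BINS = 4


class CountsError(ValueError):
    """Raised for malformed count matrices or count files."""


@dataclass
class TimeCourseCounts:
    """Raw read hit counts per transcript across the four time bins."""

    transcript_ids: list[str]
    lengths_bp: np.ndarray
    counts: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.transcript_ids = list(self.transcript_ids)
        self.lengths_bp = np.asarray(self.lengths_bp, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        n = len(self.transcript_ids)
        if len(set(self.transcript_ids)) != n:
            raise CountsError("duplicate transcript ids")
        if self.counts.shape != (n, N_BINS):
            raise CountsError(
                f"counts shape {self.counts.shape} != ({n}, {N_BINS})"
            )
        if self.lengths_bp.shape != (n,):
            raise CountsError("lengths_bp shape mismatch")
        if self.library_sizes.shape != (N_BINS,):
            raise CountsError("library_sizes must have one entry per bin")
        if n and self.lengths_bp.min() <= 0:
            raise CountsError("transcript lengths must be positive")
        if n and self.counts.min() < 0:
            raise CountsError("counts must be non-negative")
        if self.library_sizes.min() <= 0:
            raise CountsError("library sizes must be positive")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def bin_index(self, label: str) -> int:
        try:
            return BIN_LABELS.index(label)
        except ValueError:
            raise CountsError(
                f"unknown bin {label!r}; expected one of {BIN_LABELS}"
            ) from None

    def row(self, transcript_id: str) -> np.ndarray:
        return self.counts[self.transcript_ids.index(transcript_id)]


@dataclass
class NormalizedExpression:
    """Transcripts x bins matrix of reads per kilobase per million."""

    transcript_ids: list[str]
    values: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.transcript_ids, columns=list(BIN_COLUMNS)
        )


def normalize(counts: TimeCourseCounts) -> NormalizedExpression:
    """Length- and depth-normalize raw hit counts.

    value[t, s] = K[t, s] / ((length_bp[t] / 1000) * (N[s] / 1e6)) where K
    is the raw count and N the library size of bin s.
    """
    kb = counts.lengths_bp[:, None] / 1000.0
    millions = counts.library_sizes[None, :] / 1e6
    values = counts.counts / (kb * millions)
    return NormalizedExpression(list(counts.transcript_ids), values)


_REQUIRED_COLUMNS = ("transcript_id", "len_bp") + BIN_COLUMNS


def read_counts(
    path: str | Path, library_sizes_path: str | Path | None = None
) -> TimeCourseCounts:
    """Read a counts TSV; library sizes default to column sums.

    The TSV must carry columns transcript_id, len_bp, h0_2, h2_4, h4_8,
    h8_12. An optional two-column TSV (bin, library_size) supplies the
    true per-bin totals when the matrix is a subset of the full study.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CountsError(f"{path}: missing column(s) {missing}")
    dup = df["transcript_id"][df["transcript_id"].duplicated()]
    if len(dup):
        raise CountsError(
            f"{path}: duplicate transcript id {dup.iloc[0]!r} "
            f"(row {dup.index[0] + 2})"
        )
    for col in ("len_bp",) + BIN_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() | (numeric % 1 != 0)]
        if len(bad):
            raise CountsError(
                f"{path}: non-integer value {df.loc[bad[0], col]!r} in "
                f"column {col} (row {bad[0] + 2})"
            )
        df[col] = numeric.astype(np.int64)
    counts = df[list(BIN_COLUMNS)].to_numpy(dtype=np.int64)
    if library_sizes_path is not None:
        library_sizes = read_library_sizes(library_sizes_path)
    else:
        library_sizes = counts.sum(axis=0)
    return TimeCourseCounts(
        transcript_ids=df["transcript_id"].tolist(),
        lengths_bp=df["len_bp"].to_numpy(),
        counts=counts,
        library_sizes=library_sizes,
    )


def write_counts(counts: TimeCourseCounts, path: str | Path) -> None:
    df = pd.DataFrame({"transcript_id": counts.transcript_ids})
    df["len_bp"] = counts.lengths_bp
    for j, col in enumerate(BIN_COLUMNS):
        df[col] = counts.counts[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_library_sizes(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if not {"bin", "library_size"} <= set(df.columns):
        raise CountsError(f"{path}: expected columns bin, library_size")
    sizes = df.set_index("bin")["library_size"]
    try:
        return np.array(
            [int(sizes[label]) for label in BIN_LABELS], dtype=np.int64
        )
    except KeyError as exc:
        raise CountsError(f"{path}: missing bin {exc}") from None


def write_library_sizes(
    library_sizes: Sequence[int], path: str | Path
) -> None:
    pd.DataFrame(
        {"bin": list(BIN_LABELS), "library_size": list(library_sizes)}
    ).to_csv(path, sep="\t", index=False)


def write_normalized(
    expr: NormalizedExpression, path: str | Path
) -> None:
    expr.to_frame().rename_axis("transcript_id").to_csv(path, sep="\t")
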