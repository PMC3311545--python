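"""Position weight matrices and ungapped PWM-PWM alignment.

Columns are base-probability 4-vectors in fixed (A, C, G, T) order.
Alignment slides one matrix along the other in both orientations and
scores each overlap as the mean per-column Pearson correlation; an
empirical E-value comes from re-aligning against column- and
base-permuted null matrices.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motifs import (
    IUPAC_CODES,
    IupacMotif,
    MotifHit,
    as_motif,
)

BASES = "ACGT"


class PwmError(ValueError):
    """Raised for malformed matrices or impossible alignments."""


@dataclass
class PWM:
    """L x 4 base-probability matrix with a site-count provenance tag."""

    name: str
    matrix: np.ndarray = field(repr=False)
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise PwmError("PWM matrix must be L x 4")
        if (self.matrix < 0).any():
            raise PwmError("PWM entries must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise PwmError("every PWM column must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def revcomp(self) -> "PWM":
        """Column i -> L-1-i with base order (A,C,G,T) -> (T,G,C,A)."""
        return PWM(self.name + "_rc", self.matrix[::-1, ::-1], self.n_sites)


@dataclass
class PwmAlignment:
    query: str
    target: str
    offset: int
    orientation: str  # forward | revcomp
    n_overlap: int
    score: float
    e_value: float | None = None


_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def pwm_from_hits(
    hits: Sequence[MotifHit],
    sequences: Mapping[str, str],
    length: int,
    pseudocount: float = 0.25,
    name: str = "pwm",
) -> PWM:
    """Stack hit words (minus-strand hits reverse-complemented) and smooth.

    Column probability = (base count + pseudocount) / (n_sites + 4 * pc),
    which renormalizes for any pseudocount >= 0.
    """
    if not hits:
        raise PwmError("need at least one hit")
    counts = np.zeros((length, 4))
    for h in hits:
        word = sequences[h.sequence_id][h.start : h.start + length]
        if len(word) != length:
            raise PwmError(f"hit at {h.sequence_id}:{h.start} is truncated")
        word = word.upper()
        if h.strand == "-":
            word = "".join(_COMPLEMENT_BASE[c] for c in reversed(word))
        for j, b in enumerate(word):
            counts[j, BASES.index(b)] += 1
    n = len(hits)
    matrix = (counts + pseudocount) / (n + 4 * pseudocount)
    return PWM(name=name, matrix=matrix, n_sites=n)


def pwm_from_iupac(motif: IupacMotif | str, name: str | None = None) -> PWM:
    """Uniform distribution over each position's allowed bases."""
    motif = as_motif(motif)
    matrix = np.zeros((len(motif), 4))
    for j, code in enumerate(motif.pattern):
        allowed = IUPAC_CODES[code]
        for b in allowed:
            matrix[j, BASES.index(b)] = 1.0 / len(allowed)
    return PWM(name=name or motif.pattern, matrix=matrix, n_sites=0)


def _zscore_columns(matrix: np.ndarray) -> np.ndarray:
    """Per-column standardized vectors so that PCC(p, q) = zp . zq;
    zero-variance columns become zero vectors (column score 0)."""
    dev = matrix - matrix.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(dev, axis=1, keepdims=True)
    out = np.zeros_like(dev)
    nz = norm[:, 0] > 0
    out[nz] = dev[nz] / norm[nz]
    return out


def align_pwms(
    query: PWM, target: PWM, min_overlap: int = 4
) -> PwmAlignment:
    """Best ungapped offset/orientation by mean column Pearson correlation.

    Offset o aligns target column j with query column j + o. Ties break
    toward larger overlap, then smaller |offset|, then forward orientation.
    """
    if len(query) < min_overlap or len(target) < min_overlap:
        raise PwmError(
            f"PWMs must have at least min_overlap={min_overlap} columns"
        )
    zq = _zscore_columns(query.matrix)
    best: tuple | None = None
    for orientation, tmat in (
        ("forward", target.matrix),
        ("revcomp", target.revcomp().matrix),
    ):
        zt = _zscore_columns(tmat)
        lq, lt = len(zq), len(zt)
        for offset in range(-(lt - min_overlap), lq - min_overlap + 1):
            t_lo = max(0, -offset)
            t_hi = min(lt, lq - offset)
            n = t_hi - t_lo
            if n < min_overlap:
                continue
            cols = np.einsum(
                "ij,ij->i",
                zq[t_lo + offset : t_hi + offset],
                zt[t_lo:t_hi],
            )
            score = float(cols.mean())
            key = (score, n, -abs(offset), orientation == "forward")
            if best is None or key > best[0]:
                best = (
                    key,
                    PwmAlignment(
                        query=query.name,
                        target=target.name,
                        offset=offset,
                        orientation=orientation,
                        n_overlap=n,
                        score=score,
                    ),
                )
    assert best is not None
    return best[1]


def pwm_alignment_evalue(
    query: PWM,
    target: PWM,
    n_null: int = 10_000,
    seed: int | None = None,
    min_overlap: int = 4,
) -> PwmAlignment:
    """Alignment plus an empirical permutation E-value.

    Null targets permute the target's columns and, independently per
    column, the base order; the E-value is n_null times the rank fraction
    (1 + #{null >= observed}) / (n_null + 1).
    """
    alignment = align_pwms(query, target, min_overlap=min_overlap)
    rng = np.random.default_rng(seed)
    n_better = 0
    for _ in range(n_null):
        cols = rng.permutation(len(target))
        null = target.matrix[cols].copy()
        for j in range(null.shape[0]):
            null[j] = null[j, rng.permutation(4)]
        null_pwm = PWM("null", null, target.n_sites)
        if align_pwms(query, null_pwm, min_overlap).score >= alignment.score:
            n_better += 1
    p_emp = (1 + n_better) / (n_null + 1)
    alignment.e_value = n_null * p_emp
    return alignment


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    """Minimal MEME motif format writer."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            "A 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= {max(pwm.n_sites, 1)} E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PWM]:
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    n_sites = 0
    in_matrix = False

    def flush() -> None:
        nonlocal name, rows, in_matrix, n_sites
        if name is not None and rows:
            mat = np.array(rows)
            pwms.append(PWM(name, mat / mat.sum(axis=1, keepdims=True), n_sites))
        name, rows, in_matrix, n_sites = None, [], False, 0

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                name = parts[1] if len(parts) > 1 else "motif"
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
                for tok_key, tok_val in zip(line.split()[:-1], line.split()[1:]):
                    if tok_key == "nsites=":
                        n_sites = int(float(tok_val))
            elif in_matrix and line and line[0] in "0123456789.":
                rows.append([float(v) for v in line.split()])
            elif in_matrix and not line:
                in_matrix = False
    flush()
    if not pwms:
        raise PwmError(f"{path}: no motifs found")
    return pwms


def write_pwm_tsv(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tA\tC\tG\tT\n")
        for j, row in enumerate(pwm.matrix):
            fh.write(f"{j}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def write_alignment_report(
    alignments: Sequence[PwmAlignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "query\ttarget\toffset\torientation\tn_overlap\tscore\te_value\n"
        )
        for al in alignments:
            ev = "" if al.e_value is None else f"{al.e_value:.6g}"
            fh.write(
                f"{al.query}\t{al.target}\t{al.offset}\t{al.orientation}\t"
                f"{al.n_overlap}\t{al.score:.6f}\t{ev}\n"
            )
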