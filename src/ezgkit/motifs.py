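"""Degenerate-motif scanning and overrepresentation discovery.

Motifs are IUPAC strings matched on both strands of a sequence set.
Significance of a motif is a Bonferroni-style E-value: the exact binomial
upper tail of its both-strand occurrence count under an order-0 background,
multiplied by the number of candidate motifs the search space holds; the
reported "sig value" is -log10 of that E-value, so chance-level motifs
score negative.

Discovery runs in two stages: exact words of each length are enumerated
and ranked (beam stage), then each kept word — plus degenerate merges of
near-identical kept words — is greedily generalized one position at a
time to the IUPAC code that maximally increases the sig value
(degeneration stage), stopping when no single-position change helps or
the degenerate-position budget is exhausted. Because the degeneration
stage optimizes over the whole space of IUPAC patterns reachable within
that budget, the E-value multiplier counts that space, not merely the
exact words enumerated: without this the search systematically reports
positive significance on background-only input.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import binom

IUPAC_CODES: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T",
    "T": "A",
    "C": "G",
    "G": "C",
    "R": "Y",
    "Y": "R",
    "S": "S",
    "W": "W",
    "K": "M",
    "M": "K",
    "B": "V",
    "V": "B",
    "D": "H",
    "H": "D",
    "N": "N",
}

_BASES = "ACGT"
_LOG10 = math.log(10)
# Internal byte encoding: A,C,G,T = 0..3, N in sequence = 4, separator = 5.
_ENCODE = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_MATCH: dict[str, np.ndarray] = {}
for _code, _bases in IUPAC_CODES.items():
    _row = np.zeros(6, dtype=bool)
    for _b in _bases:
        _row[_BASES.index(_b)] = True
    if _code == "N":  # motif N matches sequence N; nothing else does
        _row[4] = True
    _MATCH[_code] = _row


class MotifError(ValueError):
    """Raised for invalid motifs or sequence sets."""


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate DNA motif over the IUPAC alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise MotifError("empty motif pattern")
        bad = [c for c in self.pattern if c.upper() not in IUPAC_CODES]
        if bad:
            raise MotifError(f"invalid IUPAC code(s) {bad} in {self.pattern!r}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern

    @property
    def expansion_size(self) -> int:
        return math.prod(len(IUPAC_CODES[c]) for c in self.pattern)


def as_motif(motif: IupacMotif | str) -> IupacMotif:
    return motif if isinstance(motif, IupacMotif) else IupacMotif(motif)


def iupac_expand(motif: IupacMotif | str) -> set[str]:
    """All concrete words matching the pattern."""
    motif = as_motif(motif)
    words = [""]
    for code in motif.pattern:
        words = [w + b for w in words for b in IUPAC_CODES[code]]
    return set(words)


def iupac_revcomp(motif: IupacMotif | str) -> IupacMotif:
    """Reverse complement under IUPAC code semantics."""
    motif = as_motif(motif)
    return IupacMotif(
        "".join(_COMPLEMENT[c] for c in reversed(motif.pattern))
    )


def expansion_jaccard(a: IupacMotif | str, b: IupacMotif | str) -> float:
    """Jaccard similarity of two motifs' concrete expansion sets."""
    wa, wb = iupac_expand(a), iupac_expand(b)
    union = wa | wb
    return len(wa & wb) / len(union) if union else 0.0


def candidate_space_size(length: int, max_degenerate: int) -> float:
    """Number of IUPAC patterns of a length with a bounded number of
    degenerate positions — the space the degeneration stage can reach."""
    total = 0.0
    for d in range(min(length, max_degenerate) + 1):
        total += math.comb(length, d) * (11.0**d) * (4.0 ** (length - d))
    return total


@dataclass(frozen=True)
class MotifHit:
    """One occurrence, anchored at its plus-strand start (0-based)."""

    sequence_id: str
    start: int
    strand: str


@dataclass
class BackgroundModel:
    """Order-0 base frequencies used as the overrepresentation null."""

    frequencies: np.ndarray  # A, C, G, T

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape != (4,):
            raise MotifError("background needs 4 base frequencies")
        f = np.maximum(f, 1e-6)
        self.frequencies = f / f.sum()

    @classmethod
    def from_sequences(
        cls, sequences: Mapping[str, str]
    ) -> "BackgroundModel":
        counts = np.zeros(4)
        for seq in sequences.values():
            enc = _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
            counts += np.bincount(enc, minlength=6)[:4]
        if counts.sum() == 0:
            raise MotifError("no A/C/G/T bases in background sequences")
        return cls(counts / counts.sum())

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    def code_prob(self, code: str) -> float:
        return float(
            sum(self.frequencies[_BASES.index(b)] for b in IUPAC_CODES[code])
        )

    def motif_prob(self, motif: IupacMotif | str) -> float:
        """Match probability of the pattern: equals the summed probability
        of its expansion words under the order-0 model."""
        motif = as_motif(motif)
        return math.prod(self.code_prob(c) for c in motif.pattern)


@dataclass
class MotifStats:
    """Both-strand count, -log10 E-value and coverage of one motif."""

    motif: IupacMotif
    count: int
    sig_value: float
    coverage: float
    algorithm: str = "query"
    n_candidates_tested: float = 1.0
    n_covered: int = 0

    @property
    def e_value(self) -> float:
        try:
            return 10.0 ** (-self.sig_value)
        except OverflowError:
            return math.inf


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }
    if not records:
        raise MotifError(f"{path}: no FASTA records")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _match_starts(enc: np.ndarray, pattern: str) -> np.ndarray:
    L = len(pattern)
    n = enc.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mask = _MATCH[pattern[0]][enc[:n]]
    for j in range(1, L):
        mask &= _MATCH[pattern[j]][enc[j : j + n]]
    return np.flatnonzero(mask)


def scan(
    motif: IupacMotif | str, sequences: Mapping[str, str]
) -> list[MotifHit]:
    """All both-strand occurrences; minus-strand hits are reported at
    their plus-strand start. Overlapping occurrences all count, and a
    position matching both strands yields two hits."""
    motif = as_motif(motif)
    rc = iupac_revcomp(motif)
    hits: list[MotifHit] = []
    for name, seq in sequences.items():
        enc = _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
        for pattern, strand in ((motif.pattern, "+"), (rc.pattern, "-")):
            for start in _match_starts(enc, pattern):
                hits.append(MotifHit(name, int(start), strand))
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return hits


def hit_sequences(
    hits: Sequence[MotifHit], sequences: Mapping[str, str], length: int
) -> list[str]:
    """Matched words, read 5'->3' on the hit strand."""
    out = []
    for h in hits:
        word = sequences[h.sequence_id][h.start : h.start + length]
        if h.strand == "-":
            word = "".join(_COMPLEMENT[c] for c in reversed(word))
        out.append(word)
    return out


def write_bed(
    hits: Sequence[MotifHit], motif: IupacMotif | str, path: str | Path
) -> None:
    motif = as_motif(motif)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.start + len(motif)}\t"
                f"{motif.pattern}\t0\t{h.strand}\n"
            )


class SequenceSetIndex:
    """Encoded concatenation of a sequence set for fast motif counting."""

    def __init__(self, sequences: Mapping[str, str], max_len: int = 10):
        if not sequences:
            raise MotifError("empty sequence set")
        self.names = list(sequences)
        self.lengths = [len(sequences[n]) for n in self.names]
        sep = np.full(max_len, 5, dtype=np.uint8)
        chunks, seq_idx = [], []
        for i, name in enumerate(self.names):
            enc = _ENCODE[
                np.frombuffer(sequences[name].upper().encode(), dtype=np.uint8)
            ]
            chunks += [enc, sep]
            seq_idx += [
                np.full(enc.size, i, dtype=np.int32),
                np.full(max_len, -1, dtype=np.int32),
            ]
        self.text = np.concatenate(chunks)
        self.seq_idx = np.concatenate(seq_idx)
        # One boolean lane per IUPAC code; pattern counting is then a
        # chain of shifted slice-ANDs with no per-call gather.
        self._lanes = {
            code: _MATCH[code][self.text] for code in IUPAC_CODES
        }
        self._count_cache: dict[str, int] = {}
        self._declump_cache: dict[str, int] = {}

    def n_positions(self, length: int) -> int:
        """Both-strand window count for motifs of the given length."""
        return sum(2 * max(0, n - length + 1) for n in self.lengths)

    def _mask(self, pattern: str) -> np.ndarray:
        n = self.text.size - len(pattern) + 1
        mask = self._lanes[pattern[0]][:n].copy()
        for j in range(1, len(pattern)):
            mask &= self._lanes[pattern[j]][j : j + n]
        return mask

    def count(self, pattern: str) -> int:
        """Both-strand occurrence count of a pattern across the set."""
        cached = self._count_cache.get(pattern)
        if cached is not None:
            return cached
        rc = iupac_revcomp(pattern).pattern
        total = int(self._mask(pattern).sum())
        total += int(self._mask(rc).sum())
        self._count_cache[pattern] = total
        return total

    def declumped_count(self, pattern: str) -> int:
        """Both-strand count keeping at most one occurrence per clump of
        mutually overlapping matches on a strand. Self-overlapping
        (periodic) patterns produce runs of dependent matches that break
        the binomial null; the declumped count restores it and equals the
        plain count for non-self-overlapping motifs."""
        cached = self._declump_cache.get(pattern)
        if cached is not None:
            return cached
        L = len(pattern)
        rc = iupac_revcomp(pattern).pattern
        total = 0
        for pat in (pattern, rc):
            last = -L
            for pos in np.flatnonzero(self._mask(pat)):
                if pos >= last + L:
                    total += 1
                    last = pos
        self._declump_cache[pattern] = total
        return total

    def count_and_coverage(self, pattern: str) -> tuple[int, int]:
        """(both-strand occurrence count, number of covered sequences)."""
        rc = iupac_revcomp(pattern).pattern
        starts = np.concatenate(
            [np.flatnonzero(self._mask(pattern)), np.flatnonzero(self._mask(rc))]
        )
        covered = np.unique(self.seq_idx[starts]).size
        self._count_cache[pattern] = starts.size
        return starts.size, covered


def _log10_tail(
    counts: np.ndarray, n_positions: int, probs: np.ndarray
) -> np.ndarray:
    """log10 of the exact binomial upper tail P(X >= count)."""
    counts = np.atleast_1d(np.asarray(counts))
    probs = np.minimum(np.atleast_1d(np.asarray(probs, dtype=float)), 1.0)
    out = np.zeros(counts.shape, dtype=float)
    pos = counts > 0
    if n_positions > 0 and pos.any():
        out[pos] = (
            binom.logsf(counts[pos] - 1, n_positions, probs[pos]) / _LOG10
        )
    return out


def _sig_values(
    counts, n_positions: int, probs, log10_candidates: float
) -> np.ndarray:
    return -(log10_candidates + _log10_tail(counts, n_positions, probs))


def motif_stats(
    motif: IupacMotif | str,
    sequences: Mapping[str, str],
    background: BackgroundModel | None = None,
    n_candidates_tested: float = 1.0,
    algorithm: str = "query",
) -> MotifStats:
    """Count, coverage and significance of one motif over a sequence set."""
    motif = as_motif(motif)
    if background is None:
        background = BackgroundModel.from_sequences(sequences)
    index = SequenceSetIndex(sequences, max_len=len(motif))
    count, covered = index.count_and_coverage(motif.pattern)
    n_pos = index.n_positions(len(motif))
    sig = float(
        _sig_values(
            count,
            n_pos,
            background.motif_prob(motif),
            math.log10(max(n_candidates_tested, 1.0)),
        )[0]
    )
    return MotifStats(
        motif=motif,
        count=count,
        sig_value=sig,
        coverage=covered / len(sequences),
        algorithm=algorithm,
        n_candidates_tested=n_candidates_tested,
        n_covered=covered,
    )


def _enumerate_words(
    sequences: Mapping[str, str], length: int
) -> tuple[dict[str, int], dict[str, int]]:
    """Forward-strand occurrence counts of all clean words of one length,
    total and declumped (at most one count per run of overlapping
    occurrences of the same word)."""
    counts: dict[str, int] = {}
    declumped: dict[str, int] = {}
    last_end: dict[str, int] = {}
    ok = set("ACGT")
    offset = 0
    for seq in sequences.values():
        seq = seq.upper()
        bad = {i for i, ch in enumerate(seq) if ch not in ok}
        for i in range(len(seq) - length + 1):
            if bad and any(j in bad for j in range(i, i + length)):
                continue
            w = seq[i : i + length]
            counts[w] = counts.get(w, 0) + 1
            pos = offset + i
            if pos >= last_end.get(w, -length):
                declumped[w] = declumped.get(w, 0) + 1
                last_end[w] = pos + length
        offset += len(seq) + length  # gap blocks cross-sequence overlap
    return counts, declumped


def _revcomp_word(word: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(word))


def _canonical(pattern: str) -> str:
    return min(pattern, iupac_revcomp(pattern).pattern)


def _degeneracy(pattern: Sequence[str]) -> int:
    return sum(1 for c in pattern if len(IUPAC_CODES[c]) > 1)


def _word_probs(words: list[str], background: BackgroundModel) -> np.ndarray:
    freq_by_byte = np.zeros(256)
    for i, b in enumerate(_BASES):
        freq_by_byte[ord(b)] = background.frequencies[i]
    arr = np.frombuffer("".join(words).encode(), dtype=np.uint8)
    per_char = freq_by_byte[arr].reshape(len(words), -1)
    return per_char.prod(axis=1)


def _greedy_degenerate(
    seed: str,
    index: SequenceSetIndex,
    background: BackgroundModel,
    log10_candidates: float,
    max_degenerate_positions: int,
) -> tuple[str, float]:
    """Widen one position at a time while the sig value improves."""
    n_pos = index.n_positions(len(seed))
    pattern = list(seed)

    def batch_sig(cands: list[list[str]]) -> np.ndarray:
        counts = np.array(
            [index.declumped_count("".join(c)) for c in cands]
        )
        probs = np.array(
            [
                math.prod(background.code_prob(ch) for ch in c)
                for c in cands
            ]
        )
        return _sig_values(counts, n_pos, probs, log10_candidates)

    best_sig = float(batch_sig([pattern])[0])
    while True:
        n_degen = _degeneracy(pattern)
        candidates: list[tuple[int, str]] = []
        for i, cur in enumerate(pattern):
            cur_set = set(IUPAC_CODES[cur])
            if len(cur_set) == 1 and n_degen >= max_degenerate_positions:
                continue
            for code, bases in IUPAC_CODES.items():
                if cur_set < set(bases):
                    candidates.append((i, code))
        if not candidates:
            return "".join(pattern), best_sig
        patterns = []
        for i, code in candidates:
            cand = pattern.copy()
            cand[i] = code
            patterns.append(cand)
        sigs = batch_sig(patterns)
        j = int(np.argmax(sigs))
        if sigs[j] <= best_sig + 1e-12:
            return "".join(pattern), best_sig
        pattern[candidates[j][0]] = candidates[j][1]
        best_sig = float(sigs[j])


_FLANK_PROB = 0.7


def _strip_flanks(pattern: str, background: BackgroundModel) -> str:
    """Drop terminal columns with near-unit background match probability."""
    lo, hi = 0, len(pattern)
    while hi - lo > 4 and background.code_prob(pattern[lo]) >= _FLANK_PROB:
        lo += 1
    while hi - lo > 4 and background.code_prob(pattern[hi - 1]) >= _FLANK_PROB:
        hi -= 1
    return pattern[lo:hi]


def _merge_seeds(
    kept: list[str], max_degenerate_positions: int
) -> list[str]:
    """Degenerate merges of kept words differing at few positions; gives
    the degeneration stage a head start when several concrete variants of
    one underlying motif all score well."""
    merged: list[str] = []
    seen: set[str] = set()
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept[i], kept[j]
            diff = [k for k in range(len(a)) if a[k] != b[k]]
            if not 0 < len(diff) <= max_degenerate_positions:
                continue
            pattern = list(a)
            for k in diff:
                bases = frozenset(IUPAC_CODES[a[k]]) | frozenset(
                    IUPAC_CODES[b[k]]
                )
                pattern[k] = next(
                    code
                    for code, allowed in IUPAC_CODES.items()
                    if frozenset(allowed) == bases
                )
            if _degeneracy(pattern) > max_degenerate_positions:
                continue
            joined = "".join(pattern)
            if joined not in seen:
                seen.add(joined)
                merged.append(joined)
    return merged


def discover(
    sequences: Mapping[str, str],
    background: BackgroundModel | None = None,
    length_range: tuple[int, int] = (5, 10),
    beam_width: int = 50,
    max_degenerate_positions: int = 4,
    top_n: int | None = None,
) -> list[MotifStats]:
    """Rank overrepresented motifs in a sequence set.

    Stage 1 enumerates every exact word of each length in the range and
    keeps the ``beam_width`` most significant per length; stage 2 greedily
    degenerates each kept word and each pairwise merge of similar kept
    words. Results are deduplicated by expansion-set identity (a motif
    and its reverse complement describe the same both-strand occurrence
    set) and ranked by sig value. Deterministic: the search has no random
    component.
    """
    if len(sequences) < 2:
        raise MotifError("discovery needs at least 2 sequences")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise MotifError(f"bad length range {length_range}")
    if background is None:
        background = BackgroundModel.from_sequences(sequences)
    index = SequenceSetIndex(sequences, max_len=hi)

    results: dict[str, MotifStats] = {}
    for L in range(lo, hi + 1):
        counts, declumped = _enumerate_words(sequences, L)
        if not counts:
            continue
        log10_cand = math.log10(
            candidate_space_size(L, max_degenerate_positions)
        )
        words = sorted(counts)
        totals = np.array(
            [counts[w] + counts.get(_revcomp_word(w), 0) for w in words]
        )
        dc_totals = np.array(
            [
                declumped.get(w, 0) + declumped.get(_revcomp_word(w), 0)
                for w in words
            ]
        )
        probs = _word_probs(words, background)
        n_pos = index.n_positions(L)
        sigs = _sig_values(dc_totals, n_pos, probs, log10_cand)
        order = sorted(
            range(len(words)), key=lambda i: (-sigs[i], -totals[i], words[i])
        )
        kept: list[str] = []
        kept_canon: set[str] = set()
        for i in order:
            if len(kept) >= beam_width:
                break
            canon = _canonical(words[i])
            if canon in kept_canon:
                continue
            kept_canon.add(canon)
            kept.append(words[i])
        seeds = kept + _merge_seeds(kept, max_degenerate_positions)
        for seed in seeds:
            pattern, sig = _greedy_degenerate(
                seed, index, background, log10_cand, max_degenerate_positions
            )
            # Terminal columns that match nearly everywhere (N, or any
            # code covering >= 0.7 background probability) carry almost
            # no signal but split one motif family across widths; trim
            # them so equivalent motifs collapse to one entry.
            stripped = _strip_flanks(pattern, background)
            if stripped != pattern:
                pattern = stripped
                sig = float(
                    _sig_values(
                        index.declumped_count(pattern),
                        index.n_positions(len(pattern)),
                        background.motif_prob(pattern),
                        log10_cand,
                    )[0]
                )
            canon = _canonical(pattern)
            if canon in results and results[canon].sig_value >= sig:
                continue
            count, covered = index.count_and_coverage(pattern)
            results[canon] = MotifStats(
                motif=IupacMotif(pattern),
                count=count,
                sig_value=sig,
                coverage=covered / len(sequences),
                algorithm="beam" if pattern == seed else "prism",
                n_candidates_tested=candidate_space_size(
                    L, max_degenerate_positions
                ),
                n_covered=covered,
            )

    ranked = sorted(
        results.values(),
        key=lambda s: (-s.sig_value, -s.coverage, s.motif.pattern),
    )
    return ranked[:top_n] if top_n is not None else ranked


def evaluate_query(
    motif: IupacMotif | str,
    sequence_sets: Mapping[str, Mapping[str, str]],
    background: BackgroundModel | None = None,
    n_candidates_tested: float | None = None,
    max_degenerate_positions: int = 4,
) -> dict[str, MotifStats]:
    """Score a fixed query motif against one or more sequence sets.

    ``n_candidates_tested`` defaults to the size of the discovery search
    space for the motif's length, so a query score is comparable to what
    a discovery run over the same set would report.
    """
    motif = as_motif(motif)
    if not sequence_sets:
        raise MotifError("no sequence sets supplied")
    if n_candidates_tested is None:
        n_candidates_tested = candidate_space_size(
            len(motif), max_degenerate_positions
        )
    out: dict[str, MotifStats] = {}
    for name, sequences in sequence_sets.items():
        if not sequences:
            raise MotifError(f"sequence set {name!r} is empty")
        out[name] = motif_stats(
            motif,
            sequences,
            background=background,
            n_candidates_tested=n_candidates_tested,
            algorithm="query",
        )
    return out


def stats_to_frame(stats: Sequence[MotifStats]) -> pd.DataFrame:
    """Motif table mirroring the discovery report columns."""
    return pd.DataFrame(
        {
            "motif": [s.motif.pattern for s in stats],
            "count": [s.count for s in stats],
            "sig_value": [s.sig_value for s in stats],
            "coverage": [s.coverage for s in stats],
            "algorithm": [s.algorithm for s in stats],
        }
    )


def write_motif_table(stats: Sequence[MotifStats], path: str | Path) -> None:
    stats_to_frame(stats).to_csv(path, sep="\t", index=False)
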