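"""Seeded synthetic inputs with the statistical structure the analysis
assumes: Poisson 4-bin count profiles per transcript class, transcript
annotations with intronless enrichment in the early zygotic classes, and
upstream sequences with a degenerate motif planted at a configurable
per-sequence coverage on either strand over an order-0 background.
"""

from __future__ import annotations

import json
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .motifs import IUPAC_CODES, IupacMotif, MotifHit, iupac_revcomp
from .quantify import TimeCourseCounts

MATERNAL = "maternal"
EZG_TRANSIENT = "ezg_transient"
EZG_STABLE = "ezg_stable"
FIRST_4_8 = "first_4_8"
FIRST_8_12 = "first_8_12"
SILENT = "silent"

SIM_CLASSES = (
    MATERNAL,
    EZG_TRANSIENT,
    EZG_STABLE,
    FIRST_4_8,
    FIRST_8_12,
    SILENT,
)

#: Relative temporal rate shape of each class over the four bins. Classes
#: other than maternal draw nothing at 0-2 hr by construction.
CLASS_PROFILES: dict[str, tuple[float, float, float, float]] = {
    MATERNAL: (1.0, 0.6, 0.3, 0.1),
    EZG_TRANSIENT: (0.0, 1.0, 0.4, 0.1),
    EZG_STABLE: (0.0, 0.5, 1.0, 1.4),
    FIRST_4_8: (0.0, 0.0, 1.0, 0.8),
    FIRST_8_12: (0.0, 0.0, 0.0, 1.0),
    SILENT: (0.0, 0.0, 0.0, 0.0),
}

_LOG2_SD = 2.0  # spread of per-transcript log2 abundance


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


def _default_proportions() -> dict[str, float]:
    return {
        MATERNAL: 0.55,
        EZG_TRANSIENT: 0.02,
        EZG_STABLE: 0.02,
        FIRST_4_8: 0.05,
        FIRST_8_12: 0.05,
        SILENT: 0.31,
    }


@dataclass
class SimulationConfig:
    n_transcripts: int = 2000
    class_proportions: dict[str, float] = field(
        default_factory=_default_proportions
    )
    mean_expression_log2: float = 6.0
    library_sizes: tuple[int, int, int, int] = (
        500_000,
        500_000,
        500_000,
        500_000,
    )
    transcript_length_range: tuple[int, int] = (500, 3000)
    p_intronless_ezg: float = 0.33
    p_intronless_background: float = 0.10
    upstream_length: int = 400
    motif_consensus: str = "VBRGGTA"
    motif_coverage: float = 0.635
    gc_content: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise SimulationError("n_transcripts must be positive")
        unknown = set(self.class_proportions) - set(SIM_CLASSES)
        if unknown:
            raise SimulationError(f"unknown classes {sorted(unknown)}")
        values = list(self.class_proportions.values())
        if any(not math.isfinite(v) or v < 0 or v > 1 for v in values):
            raise SimulationError("class proportions must lie in [0, 1]")
        if abs(sum(values) - 1.0) > 1e-9:
            raise SimulationError("class proportions must sum to 1")
        if len(self.library_sizes) != 4 or any(
            s <= 0 for s in self.library_sizes
        ):
            raise SimulationError("need 4 positive library sizes")
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise SimulationError("bad transcript length range")
        for p in (
            self.p_intronless_ezg,
            self.p_intronless_background,
            self.motif_coverage,
            self.gc_content,
        ):
            if not (math.isfinite(p) and 0.0 <= p <= 1.0):
                raise SimulationError(f"probability {p} outside [0, 1]")
        if not math.isfinite(self.mean_expression_log2):
            raise SimulationError("mean_expression_log2 must be finite")
        IupacMotif(self.motif_consensus)  # validates the pattern
        if self.upstream_length < len(self.motif_consensus):
            raise SimulationError(
                "upstream_length shorter than the motif consensus"
            )

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["library_sizes"] = list(self.library_sizes)
        data["transcript_length_range"] = list(self.transcript_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("library_sizes", "transcript_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Labels recorded while simulating, for recovery tests."""

    class_of: dict[str, str] = field(default_factory=dict)
    planted_hits: list[MotifHit] = field(default_factory=list)
    intronless_of: dict[str, bool] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            class_of={**self.class_of, **other.class_of},
            planted_hits=self.planted_hits + other.planted_hits,
            intronless_of={**self.intronless_of, **other.intronless_of},
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "class_of": self.class_of,
                    "planted_hits": [
                        [h.sequence_id, h.start, h.strand]
                        for h in self.planted_hits
                    ],
                    "intronless_of": self.intronless_of,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            class_of=data.get("class_of", {}),
            planted_hits=[
                MotifHit(s, int(i), st)
                for s, i, st in data.get("planted_hits", [])
            ],
            intronless_of={
                k: bool(v) for k, v in data.get("intronless_of", {}).items()
            },
        )


def transcript_id(i: int) -> str:
    return f"TX{i:05d}"


def gene_id_of(tid: str) -> str:
    return "GN" + tid[2:]


def _assign_classes(config: SimulationConfig, rng) -> list[str]:
    """Deterministic largest-remainder allocation, then a seeded shuffle."""
    n = config.n_transcripts
    raw = {
        c: config.class_proportions.get(c, 0.0) * n for c in SIM_CLASSES
    }
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    leftovers = sorted(
        SIM_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True
    )
    for c in leftovers[:short]:
        counts[c] += 1
    labels = [c for c in SIM_CLASSES for _ in range(counts[c])]
    return [labels[i] for i in rng.permutation(n)]


def simulate_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TimeCourseCounts, GroundTruth]:
    """Poisson counts with class-specific temporal rate profiles.

    Rates are scaled per bin so that expected column sums match the
    configured library sizes; classes with zero rate in a bin can never
    produce a count there.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    labels = _assign_classes(config, rng)
    levels = np.exp2(
        rng.normal(config.mean_expression_log2, _LOG2_SD, size=n)
    )
    rates = np.array([CLASS_PROFILES[lab] for lab in labels]) * levels[:, None]
    for s in range(4):
        total = rates[:, s].sum()
        if total > 0:
            rates[:, s] *= config.library_sizes[s] / total
    counts = rng.poisson(rates)
    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    ids = [transcript_id(i) for i in range(n)]
    tc = TimeCourseCounts(
        transcript_ids=ids,
        lengths_bp=lengths,
        counts=counts,
        library_sizes=np.asarray(config.library_sizes),
    )
    truth = GroundTruth(class_of=dict(zip(ids, labels)))
    return tc, truth


def simulate_upstream(
    config: SimulationConfig,
    n_sequences: int,
    ids: Sequence[str] | None = None,
    plant_ids: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Background sequences with the consensus motif planted by overwrite.

    Each sequence (restricted to ``plant_ids`` when given) receives, with
    probability motif_coverage, one concrete expansion of the consensus at
    a uniform position on a uniform strand. Background bases are i.i.d.
    with the configured GC fraction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_sequences <= 0:
        raise SimulationError("n_sequences must be positive")
    motif = IupacMotif(config.motif_consensus)
    L = config.upstream_length
    if L < len(motif):
        raise SimulationError("motif longer than upstream sequence")
    if ids is None:
        ids = [f"SEQ{i:05d}" for i in range(n_sequences)]
    elif len(ids) != n_sequences:
        raise SimulationError("ids length != n_sequences")
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    truth = GroundTruth()
    for name in ids:
        seq = rng.choice(bases, size=L, p=base_p)
        plantable = plant_ids is None or name in plant_ids
        if plantable and rng.random() < config.motif_coverage:
            word = "".join(
                IUPAC_CODES[c][rng.integers(len(IUPAC_CODES[c]))]
                for c in motif.pattern
            )
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, L - len(motif) + 1))
            inserted = (
                word
                if strand == "+"
                else str(iupac_revcomp(word))
            )
            seq[start : start + len(motif)] = list(inserted)
            truth.planted_hits.append(MotifHit(name, start, strand))
        sequences[name] = "".join(seq)
    return sequences, truth


def simulate_annotations(
    config: SimulationConfig,
    truth: GroundTruth,
    lengths: Mapping[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """One gene per transcript; intronless flags enriched in ezg classes.

    Intron counts are 0 for intronless genes and 1 + Poisson(2) otherwise.
    ``lengths`` ties annotation lengths to an existing count matrix.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not truth.class_of:
        raise SimulationError("ground truth carries no class labels")
    lo, hi = config.transcript_length_range
    rows = []
    intronless_of: dict[str, bool] = {}
    for tid, label in truth.class_of.items():
        gene = gene_id_of(tid)
        p0 = (
            config.p_intronless_ezg
            if label in (EZG_TRANSIENT, EZG_STABLE)
            else config.p_intronless_background
        )
        intronless = bool(rng.random() < p0)
        n_introns = 0 if intronless else 1 + int(rng.poisson(2.0))
        length = (
            int(lengths[tid])
            if lengths is not None
            else int(rng.integers(lo, hi + 1))
        )
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": gene,
                "n_introns": n_introns,
                "length_bp": length,
            }
        )
        intronless_of[gene] = intronless
    annotations = pd.DataFrame(rows)
    return annotations, GroundTruth(
        class_of=dict(truth.class_of),
        planted_hits=list(truth.planted_hits),
        intronless_of=intronless_of,
    )


def simulate_bundle(
    config: SimulationConfig,
) -> tuple[TimeCourseCounts, dict[str, str], pd.DataFrame, GroundTruth]:
    """Counts, upstream sequences and annotations from one generator.

    Upstream sequences cover every transcript; the motif is planted (at
    the configured coverage) only in sequences of ezg-class transcripts.
    """
    rng = np.random.default_rng(config.seed)
    counts, truth = simulate_counts(config, rng=rng)
    lengths = dict(zip(counts.transcript_ids, counts.lengths_bp))
    annotations, truth = simulate_annotations(
        config, truth, lengths=lengths, rng=rng
    )
    ezg_ids = {
        t
        for t, lab in truth.class_of.items()
        if lab in (EZG_TRANSIENT, EZG_STABLE)
    }
    sequences, seq_truth = simulate_upstream(
        config,
        n_sequences=config.n_transcripts,
        ids=counts.transcript_ids,
        plant_ids=ezg_ids,
        rng=rng,
    )
    return counts, sequences, annotations, truth.merge(seq_truth)
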