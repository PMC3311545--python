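"""End-to-end orchestration: normalize -> classify -> test -> structure ->
motif discovery -> PWM alignment, with a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from . import __version__
from . import mars as mars_mod
from . import motifs as motifs_mod
from . import pwm as pwm_mod
from . import quantify, structure, temporal

log = logging.getLogger("ezgkit.pipeline")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot run."""


@dataclass
class PipelineConfig:
    counts: str
    annotations: str
    upstream_fasta: str
    out_dir: str
    library_sizes: str | None = None
    background_fasta: str | None = None
    pseudocount: float = 1.0
    thresholds: tuple[float, ...] = (0.001, 0.05)
    variance: str = "conditional"
    ezg_threshold: float = 0.001
    motif_length_range: tuple[int, int] = (5, 10)
    beam_width: int = 50
    max_degenerate_positions: int = 4
    query_motif: str = "VBRGGTA"
    min_overlap: int = 4
    n_null: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds = tuple(sorted(float(t) for t in self.thresholds))
        self.motif_length_range = tuple(self.motif_length_range)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        "counts": config.counts,
        "annotations": config.annotations,
        "upstream_fasta": config.upstream_fasta,
    }
    if config.library_sizes:
        inputs["library_sizes"] = config.library_sizes
    if config.background_fasta:
        inputs["background_fasta"] = config.background_fasta
    for name, path in inputs.items():
        if not Path(path).exists():
            raise PipelineError(f"stage=inputs missing {name} file: {path}")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
        "headline": {},
    }

    log.info("stage=normalize")
    counts = quantify.read_counts(config.counts, config.library_sizes)
    expr = quantify.normalize(counts)
    quantify.write_normalized(expr, out / "normalized.tsv")

    log.info("stage=mars")
    results = mars_mod.mars_table(
        counts,
        ("0-2", "2-4"),
        pseudocount=config.pseudocount,
        variance=config.variance,
    )
    mars_mod.write_mars_table(
        results, out / "mars_0-2_vs_2-4.tsv", thresholds=config.thresholds
    )

    log.info("stage=classify")
    calls = temporal.call_ezgs(counts, results, config.thresholds)
    temporal.classification_frame(counts, results, config.thresholds).to_csv(
        out / "classification.tsv", sep="\t", index=False
    )
    pairs = temporal.default_group_pairs()
    by_pair = {
        group: mars_mod.mars_table(
            counts,
            pair,
            pseudocount=config.pseudocount,
            variance=config.variance,
        )
        for group, pair in pairs.items()
    }
    groups = temporal.group_by_first_presence(
        counts, by_pair, threshold=config.ezg_threshold
    )
    with open(out / "ezg_calls.json", "w") as fh:
        json.dump(
            {
                "candidates": sorted(calls.candidates),
                "significant": {
                    str(t): sorted(s) for t, s in calls.significant.items()
                },
                "first_presence_groups": {
                    g: sorted(s) for g, s in groups.items()
                },
            },
            fh,
            indent=1,
        )
    manifest["headline"]["n_candidates"] = len(calls.candidates)
    for thr, ids in calls.significant.items():
        manifest["headline"][f"n_significant_p<{thr}"] = len(ids)

    log.info("stage=structure")
    annotations = structure.read_annotations(config.annotations)
    tx2gene = dict(
        zip(annotations["transcript_id"], annotations["gene_id"])
    )
    status = structure.gene_intron_status(annotations)
    intron_counts = structure.gene_intron_counts(annotations)
    gene_groups = {
        "ezg": set(
            temporal.collapse_to_genes(
                sorted(calls.significant[config.ezg_threshold]), tx2gene
            )
        ),
        "4-8": set(
            temporal.collapse_to_genes(sorted(groups["4-8"]), tx2gene)
        ),
        "8-12": set(
            temporal.collapse_to_genes(sorted(groups["8-12"]), tx2gene)
        ),
    }
    summaries, tests = structure.compare_groups(
        status, gene_groups, intron_counts=intron_counts
    )
    structure.summaries_to_frame(summaries).to_csv(
        out / "structure_summary.tsv", sep="\t", index=False
    )
    tests.to_csv(out / "structure_tests.tsv", sep="\t", index=False)
    manifest["headline"]["fraction_intronless"] = {
        s.group: s.fraction_intronless for s in summaries
    }

    log.info("stage=discover")
    upstream = motifs_mod.read_fasta(config.upstream_fasta)
    ezg_transcripts = sorted(calls.significant[config.ezg_threshold])
    gene_reps = temporal.collapse_to_genes(ezg_transcripts, tx2gene)
    query_ids = [t for t in gene_reps.values() if t in upstream]
    if len(query_ids) < 2:
        raise PipelineError(
            "stage=discover fewer than 2 EZG upstream sequences available"
        )
    query_set = {t: upstream[t] for t in query_ids}
    if config.background_fasta:
        background = motifs_mod.BackgroundModel.from_sequences(
            motifs_mod.read_fasta(config.background_fasta)
        )
    else:
        background = motifs_mod.BackgroundModel.from_sequences(query_set)
    ranked = motifs_mod.discover(
        query_set,
        background=background,
        length_range=config.motif_length_range,
        beam_width=config.beam_width,
        max_degenerate_positions=config.max_degenerate_positions,
    )
    motifs_mod.write_motif_table(ranked[:50], out / "motif_table.tsv")
    manifest["headline"]["top_motifs"] = [
        {
            "motif": s.motif.pattern,
            "count": s.count,
            "sig_value": round(s.sig_value, 3),
            "coverage": round(s.coverage, 4),
            "algorithm": s.algorithm,
        }
        for s in ranked[:10]
    ]

    log.info("stage=pwm")
    pwms = []
    alignments = []
    if ranked:
        top = ranked[0]
        hits = motifs_mod.scan(top.motif, query_set)
        motifs_mod.write_bed(hits, top.motif, out / "top_motif_hits.bed")
        if hits:
            top_pwm = pwm_mod.pwm_from_hits(
                hits, query_set, length=len(top.motif), name=top.motif.pattern
            )
            pwms.append(top_pwm)
            query_pwm = pwm_mod.pwm_from_iupac(config.query_motif)
            pwms.append(query_pwm)
            alignments.append(
                pwm_mod.pwm_alignment_evalue(
                    top_pwm,
                    query_pwm,
                    n_null=config.n_null,
                    seed=config.seed,
                    min_overlap=config.min_overlap,
                )
            )
    if pwms:
        pwm_mod.write_meme(pwms, out / "motifs.meme")
    pwm_mod.write_alignment_report(alignments, out / "pwm_alignments.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("stage=done")
    return manifest
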