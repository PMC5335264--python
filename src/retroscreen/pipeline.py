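"""Pipeline orchestration and assembly summary statistics.

The pipeline chains the stages of a retroposon presence/absence study:
assembly summary statistics -> locus selection and extraction ->
multi-directional alignment screening -> insertion significance test.
Inputs come either from files (contig FASTA, RepeatMasker tables, AXT
alignments) or from the built-in simulator, configured in YAML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import fastcoex
from .axt import parse_axt
from .kksc import MarkerCounts, multidirectional_test
from .repeatmasker import parse_repeatmasker_out
from .screen import ScreenConfig
from .screen import screen as _run_screen
from .screen import write_candidate_table
from .simulate import DEFAULT_TREE, emit_axt, emit_repeatmasker
from .simulate import simulate as _simulate

__all__ = ["AssemblyStats", "assembly_stats", "run_pipeline", "PipelineError"]

logger = logging.getLogger("retroscreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass(frozen=True)
class AssemblyStats:
    """Contig length summary with Nxx lengths and Lxx counts.

    ``nxx_length[f]`` is the length of the contig at which the
    descending cumulative length first reaches fraction ``f`` of the
    total; ``lxx_count[f]`` is how many contigs that takes.  The two are
    distinct statistics (lengths are non-increasing in ``f``, counts
    non-decreasing) and both are always reported.
    """

    contig_count: int
    total_length: int
    min_length: int
    mean_length: float
    max_length: int
    nxx_length: dict[float, int]
    lxx_count: dict[float, int]

    def as_dict(self) -> dict:
        return {
            "contig_count": self.contig_count,
            "total_length": self.total_length,
            "min_length": self.min_length,
            "mean_length": self.mean_length,
            "max_length": self.max_length,
            "nxx_length": {f"N{int(100 * f)}": v for f, v in self.nxx_length.items()},
            "lxx_count": {f"L{int(100 * f)}": v for f, v in self.lxx_count.items()},
        }


def assembly_stats(
    lengths: Sequence[int],
    fractions: Sequence[float] = (0.25, 0.5, 0.75),
    min_length_filter: int = 200,
) -> AssemblyStats:
    """Summary statistics of a contig length distribution.

    Contigs shorter than ``min_length_filter`` are dropped first; an
    empty set after filtering is an error.
    """
    kept = np.asarray([x for x in lengths if x >= min_length_filter], dtype=np.int64)
    if kept.size == 0:
        raise ValueError(
            f"no contigs of length >= {min_length_filter} (from {len(lengths)} input lengths)"
        )
    desc = np.sort(kept)[::-1]
    total = int(desc.sum())
    cumulative = np.cumsum(desc)
    nxx: dict[float, int] = {}
    lxx: dict[float, int] = {}
    for f in fractions:
        idx = int(np.searchsorted(cumulative, f * total))
        nxx[f] = int(desc[idx])
        lxx[f] = idx + 1
    return AssemblyStats(
        contig_count=int(kept.size),
        total_length=total,
        min_length=int(desc[-1]),
        mean_length=float(desc.mean()),
        max_length=int(desc[0]),
        nxx_length=nxx,
        lxx_count=lxx,
    )


def _package_version() -> str:
    try:
        return version("retroscreen")
    except PackageNotFoundError:
        return "unknown"


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return result

        return run

    return wrap


def _load_inputs(config: Mapping) -> tuple[dict[str, str], list, dict[str, list]]:
    """Resolve contigs, reference repeat records, and alignments from config."""
    if "simulate" in config:
        sim_cfg = dict(config["simulate"])
        ins = sim_cfg.pop("insertions", None)
        if ins is not None:
            ins = {tuple(sorted(k.split("/"))): int(v) for k, v in ins.items()}
        dataset = _simulate(
            tree=sim_cfg.get("tree", DEFAULT_TREE),
            genome_length=int(sim_cfg.get("genome_length", 100_000)),
            insertion_rate=float(sim_cfg.get("insertion_rate", 2.0)),
            subst_rate=float(sim_cfg.get("subst_rate", 0.02)),
            ils_prob=float(sim_cfg.get("ils_prob", 0.05)),
            seed=config.get("seed"),
            insertions=ins,
        )
        reference = config["reference"]
        contigs = {reference: dataset.genomes[reference]}
        repeats = parse_repeatmasker_out(
            emit_repeatmasker(dataset, reference).splitlines()
        )
        alignments = {
            taxon: parse_axt(emit_axt(dataset, reference, taxon).splitlines())
            for taxon in dataset.taxa
            if taxon != reference
        }
        return contigs, repeats, alignments
    contigs = fastcoex.read_contigs(config["contigs"])
    with open(config["repeats"]) as fh:
        repeats = parse_repeatmasker_out(fh)
    alignments = {}
    for taxon, path in config.get("alignments", {}).items():
        with open(path) as fh:
            alignments[taxon] = parse_axt(fh)
    return contigs, repeats, alignments


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Run stats -> extract -> screen(s) -> significance and write a report.

    Writes ``summary.json`` (deterministic for a fixed config and seed),
    per-stage outputs, and ``pipeline.log`` under *outdir*.  A stage
    failure raises :class:`PipelineError` naming the stage; outputs of
    completed stages are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("retroscreen %s", _package_version())
    logger.info("seed=%s", config.get("seed"))
    logger.info("config=%s", json.dumps(config, sort_keys=True, default=str))
    try:
        contigs, repeats, alignments = _stage("inputs")(_load_inputs)(config)

        stats = _stage("stats")(assembly_stats)(
            [len(s) for s in contigs.values()],
            min_length_filter=int(config.get("min_contig_length", 200)),
        )

        families = frozenset(config.get("families", fastcoex.DEFAULT_FAMILIES))

        def extract():
            specs = fastcoex.select_informative(
                repeats,
                {name: len(seq) for name, seq in contigs.items()},
                families=families,
                min_flank=int(config.get("min_flank", 50)),
            )
            loci = fastcoex.extract_sequences(
                contigs, specs, extract_flank=int(config.get("extract_flank", 250))
            )
            with open(outdir / "loci.fa", "w") as fh:
                fastcoex.write_loci_fasta(loci, fh)
            with open(outdir / "loci.tsv", "w") as fh:
                fastcoex.write_locus_table(specs, fh)
            return specs, loci

        specs, _loci = _stage("extract")(extract)()
        summary = fastcoex.family_count_summary(specs)

        screen_reports = []
        for screen_cfg in config.get("screens", []):
            name = screen_cfg["name"]

            def run_screen(screen_cfg=screen_cfg, name=name):
                cfg = ScreenConfig(
                    reference=config["reference"],
                    repeats=repeats,
                    alignments=alignments,
                    pattern_table=screen_cfg["patterns"],
                    outgroups=screen_cfg.get("outgroups", config.get("outgroups", [])),
                    families=families,
                    absence_threshold=float(config.get("absence_threshold", 0.70)),
                    presence_threshold=float(config.get("presence_threshold", 0.30)),
                    min_coverage=float(config.get("min_coverage", 0.80)),
                )
                result = _run_screen(cfg)
                with open(outdir / f"screen.{name}.tsv", "w") as fh:
                    write_candidate_table(result, fh)
                counts = result.counts_vector()
                extra = screen_cfg.get("extra_markers", {})
                for i, label in enumerate(result.pattern_labels):
                    counts[i] += int(extra.get(label, 0))
                report = {
                    "name": name,
                    "pattern_counts": result.pattern_counts,
                    "counts": counts,
                    "labels": list(result.pattern_labels),
                }
                if sum(counts) == 0:
                    report["significance"] = None
                    report["verdict"] = "no markers"
                else:
                    sig = multidirectional_test(
                        MarkerCounts(*counts[:3], labels=tuple(result.pattern_labels[:3])),
                        alpha=float(config.get("alpha", 0.05)),
                    )
                    report["significance"] = sig.as_dict()
                    report["verdict"] = sig.verdict
                return report

            screen_reports.append(_stage(f"screen:{name}")(run_screen)())

        report = {
            "version": _package_version(),
            "seed": config.get("seed"),
            "assembly_stats": stats.as_dict(),
            "n_selected_loci": summary.total,
            "family_counts": summary.as_dict(),
            "screens": screen_reports,
        }
        (outdir / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
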