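"""End-to-end orchestration: seeds -> extensions -> filters -> candidates.

``infer_genes`` runs the inference funnel on one in-memory CDR3 dataset and
reports per-stage counts; ``run_pipeline`` wraps it with file I/O, optional
consensus construction, cross-dataset consolidation, database annotation
and usage computation, writing all stage outputs plus a JSON manifest.
Inference contains no randomness: reruns on identical inputs and config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import annotate_candidates
from .config import PipelineConfig
from .core import ExtensionEngine, select_seeds
from .filtering import (
    PositionedExtension,
    build_similarity_graph,
    classify_by_position,
    filter_unidirectional,
    mean_relative_position,
    merge_across_datasets,
    merge_cliques,
    relative_position,
)
from .io import CDR3Set, GermlineDB, build_consensus_cdr3s, count_kmers, read_cdr3_dataset
from .usage import compute_usage

logger = logging.getLogger(__name__)


@dataclass
class InferenceResult:
    candidates: list[str]
    funnel: dict[str, int]
    extensions: list = field(default_factory=list)
    positioned: list = field(default_factory=list)


def _mean_rp(ext_seq: str, engine: ExtensionEngine) -> tuple[float, int]:
    """Mean relative position using the engine's k-mer postings for speed."""
    if len(ext_seq) >= engine.seed_len:
        pool = engine._postings.get(ext_seq[: engine.seed_len], [])
    else:
        pool = list(engine.cdr3s)
    total, n = 0.0, 0
    for c in pool:
        if ext_seq in c:
            total += relative_position(ext_seq, c)
            n += 1
    return (total / n if n else float("nan")), n


def infer_genes(cdr3s: CDR3Set, config: PipelineConfig | None = None) -> InferenceResult:
    """Run the inference funnel on one CDR3 dataset."""
    cfg = config or PipelineConfig()
    kmers = count_kmers(cdr3s, cfg.k)
    seeds = select_seeds(kmers, cfg.num_seeds)
    engine = ExtensionEngine(cdr3s, seed_len=cfg.k)

    extensions = []
    for seed in seeds:
        extensions.extend(
            engine.extend(
                seed, alpha=cfg.alpha, branch_alpha=cfg.branch_alpha, max_len=cfg.max_len
            )
        )
    bidir = filter_unidirectional(extensions, cfg.keep_unidirectional)

    # collapse exact duplicates, keeping the highest-support record
    uniq: dict[str, object] = {}
    for ext in sorted(bidir, key=lambda e: (-e.support, e.sequence)):
        uniq.setdefault(ext.sequence, ext)
    positioned = []
    for seq, ext in sorted(uniq.items()):
        rp, n = _mean_rp(seq, engine)
        positioned.append(PositionedExtension(extension=ext, mean_rp=rp, n_cdr3s=n))
    positioned = [p for p in positioned if p.n_cdr3s > 0]
    classify_by_position(positioned)
    central = [p.extension.sequence for p in positioned if p.segment_class == "D"]

    graph = build_similarity_graph(central, max_dist=cfg.max_dist)
    candidates = merge_cliques(graph, engine=engine, alpha=cfg.alpha, max_len=cfg.max_len)

    funnel = {
        "seeds": len(seeds),
        "extensions": len(extensions),
        "after_unidirectional_filter": len(bidir),
        "unique": len(uniq),
        "central_cluster": len(central),
        "post_merge": len(candidates),
    }
    return InferenceResult(
        candidates=candidates, funnel=funnel, extensions=extensions, positioned=positioned
    )


def run_pipeline(
    config: PipelineConfig,
    inputs: list,
    out_dir: str | Path,
    db: GermlineDB | str | Path | None = None,
    input_format: str = "fasta",
) -> dict:
    """Full pipeline over one or more datasets; returns the manifest dict.

    ``inputs`` may mix file paths and in-memory CDR3Sets. Datasets below
    ``min_dataset_size`` are skipped with a logged reason (not fatal).
    Stage outputs land in ``out_dir``: candidates per dataset and
    consolidated (FASTA), annotation TSV and usage TSV when a database is
    given, and ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(db, (str, Path)):
        db = GermlineDB.from_fasta(db)

    datasets: list[CDR3Set] = []
    skipped: list[str] = []
    for item in inputs:
        if isinstance(item, CDR3Set):
            ds = item
        else:
            ds = read_cdr3_dataset(item, format=input_format, min_size=config.min_dataset_size)
        if config.consensus_mismatches > 0:
            ds = build_consensus_cdr3s(ds, config.consensus_mismatches)
        if len(ds) < config.min_dataset_size:
            logger.warning(
                "skipping dataset %s: %d distinct CDR3s < %d",
                ds.label, len(ds), config.min_dataset_size,
            )
            skipped.append(ds.label)
            continue
        datasets.append(ds)
    if not datasets:
        raise ValueError("no dataset passes the min_dataset_size filter")

    t0 = time.time()
    per_dataset = {}
    candidate_lists = []
    for ds in datasets:
        res = infer_genes(ds, config)
        per_dataset[ds.label] = res.funnel
        candidate_lists.append(res.candidates)
        with open(out_dir / f"candidates_{ds.label}.fasta", "w") as fh:
            for i, c in enumerate(res.candidates):
                fh.write(f">{ds.label}|cand_{i}\n{c}\n")

    consolidated = (
        merge_across_datasets(candidate_lists, max_dist=config.max_dist)
        if len(candidate_lists) > 1
        else candidate_lists[0]
    )
    with open(out_dir / "candidates_consolidated.fasta", "w") as fh:
        for i, c in enumerate(consolidated):
            fh.write(f">cand_{i}\n{c}\n")

    logger.info("inference wall time %.1fs", time.time() - t0)
    manifest = {
        "config": config.digest(),
        "per_dataset_funnel": per_dataset,
        "skipped_datasets": skipped,
        "n_consolidated": len(consolidated),
    }

    if db is not None and len(db) > 0:
        annotated = annotate_candidates(
            consolidated, db, config.extension, config.identity_threshold
        )
        with open(out_dir / "annotation.tsv", "w") as fh:
            fh.write("candidate\tclass\tclosest\tidentity\toffset\n")
            for a in annotated:
                closest = f"{a.closest[0]}*{a.closest[1]}" if a.closest else ""
                fh.write(
                    f"{a.sequence}\t{a.classification}\t{closest}\t{a.identity:.1f}\t{a.offset}\n"
                )
        manifest["classification_counts"] = {
            label: sum(a.classification == label for a in annotated)
            for label in ("in_db", "novel_variation", "novel_gene")
        }
        usage = compute_usage(datasets[0], db, config.k_min)
        usage.to_frame().to_csv(out_dir / "usage.tsv", sep="\t", index=False)
        manifest["traceable_fraction"] = round(usage.traceable_fraction, 4)
    else:
        logger.info("no germline database given: annotation stage skipped")

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
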