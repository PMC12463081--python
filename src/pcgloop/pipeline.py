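"""End-to-end pipeline runner with a reproducibility manifest.

Chains simulate -> design-probes -> classify -> compare -> enrich ->
expression in dependency order. Every run writes a ``RunManifest``
(``manifest.json``): tool version, timestamp, config hash, input file
checksums, and per-stage output paths with summary counts. Seeds are
always explicit in the config, never wall-clock derived, so re-running
with identical inputs reproduces identical summary counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from .enrichment import enrichment_test
from .expression import (
    assign_genes_to_regions,
    bait_region_groups,
    expression_proportions,
    genes_at_loop_anchors,
    upregulated_fraction_by_fate,
)
from .fragments import digest_genome, map_regions_to_fragments
from .intervals import GenomicInterval
from .loops import bait_class_map, class_summary, classify_loops, type_baits, loops_from_intervals
from .mutant import (
    FATE_CELLS,
    H2AUB_MARK,
    K27_MARK,
    anchor_venn,
    association_test,
    characterize_new_loops,
    compute_hm_changes,
    cross_classify,
    fate_table,
    hm_fates,
    loop_fates,
    match_loops,
)
from .probes import design_probes_for_regions
from .synthetic import SimConfig, generate

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage; return (and write) the manifest.

    ``config`` is a flat mapping with a ``seed`` and either a
    ``simulate`` section (synthetic-data overrides, possibly empty) or an
    ``inputs`` section naming existing files. A failure in any stage
    raises :class:`PipelineError` after writing a partial manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict[str, Any] = {
        "tool": "pcgloop",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_hash": _config_hash(config),
        "input_checksums": {},
        "stages": [],
    }

    def record(stage: str, outputs: dict[str, str], counts: dict[str, Any]) -> None:
        manifest["stages"].append(
            {"stage": stage, "outputs": outputs, "counts": counts}
        )

    def finish(status: str) -> dict:
        manifest["status"] = status
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest

    # -- pre-flight --------------------------------------------------------
    inputs = config.get("inputs")
    if inputs is not None:
        missing = [p for p in inputs.values() if not Path(p).exists()]
        if missing:
            finish("failed")
            raise PipelineError(f"missing input files: {missing}")
        paths = dict(inputs)
    else:
        paths = {}

    try:
        # -- stage 1: simulate --------------------------------------------
        if inputs is None:
            sim_conf = SimConfig.from_dict(
                {"seed": seed, **config.get("simulate", {})}
            )
            sim = generate(sim_conf)
            paths = sim.write(out / "sim")
            record(
                "simulate",
                {k: str(v) for k, v in paths.items()},
                {
                    "n_fragments": len(sim.fragments),
                    "n_loops_wt": len(sim.loops_wt),
                    "n_loops_mut": len(sim.loops_mut),
                },
            )
        for key, p in paths.items():
            manifest["input_checksums"][key] = _sha256(Path(p))

        genome = pio.read_fasta(paths["genome"])
        fragments = digest_genome(genome)
        h2aub_peaks = pio.read_bed_intervals(paths["h2aub_peaks"])
        k27_peaks = pio.read_bed_intervals(paths["k27_peaks"])

        # -- stage 2: design-probes ---------------------------------------
        probes = design_probes_for_regions(
            h2aub_peaks, region_ids=[f"peak{i}" for i in range(len(h2aub_peaks))]
        )
        probe_path = out / "probes.bed"
        pio.write_bed(
            [
                pio.BedRecord(
                    p.interval, f"{p.source_region_id}:{j}", float(p.clipped)
                )
                for j, p in enumerate(probes)
            ],
            probe_path,
        )
        record("design-probes", {"probes": str(probe_path)}, {"n_probes": len(probes)})

        # -- stage 3: classify --------------------------------------------
        bait_ids = map_regions_to_fragments(h2aub_peaks, fragments)
        baits = type_baits(bait_ids, fragments, k27_peaks)
        classes = bait_class_map(baits)

        classified = {}
        counts3: dict[str, Any] = {"n_baits": len(baits)}
        outputs3 = {}
        for name in ("wt", "mut"):
            table = pio.read_loop_table(paths[f"loops_{name}"])
            loops = loops_from_intervals(table, fragments)
            cls, n_dropped = classify_loops(loops, classes)
            classified[name] = cls
            path = out / f"classified_loops_{name}.tsv"
            pio.write_table(cls, path)
            outputs3[name] = str(path)
            counts3[f"n_loops_{name}"] = len(cls)
            counts3[f"n_dropped_{name}"] = n_dropped
        counts3["wt_summary"] = class_summary(classified["wt"])
        record("classify", outputs3, counts3)

        # -- stage 4: compare ----------------------------------------------
        wt_cls, mut_cls = classified["wt"], classified["mut"]
        matched = match_loops(wt_cls, mut_cls)
        lfate = loop_fates(wt_cls, mut_cls)
        wt_anchor_ids = set(wt_cls["anchorA"]) | set(wt_cls["anchorB"])
        bait_anchor_ids = sorted(wt_anchor_ids & set(classes))
        changes = pd.concat(
            [
                compute_hm_changes(
                    bait_anchor_ids, fragments,
                    pio.read_bedgraph(paths["h2aub_wt"]),
                    pio.read_bedgraph(paths["h2aub_mut"]), H2AUB_MARK,
                ),
                compute_hm_changes(
                    bait_anchor_ids, fragments,
                    pio.read_bedgraph(paths["k27_wt"]),
                    pio.read_bedgraph(paths["k27_mut"]), K27_MARK,
                ),
            ],
            ignore_index=True,
        )
        hfate = hm_fates(wt_cls, changes, classes)
        cells = cross_classify(lfate, hfate)
        assoc = association_test(fate_table(lfate, hfate))
        new_info = characterize_new_loops(matched["new"], classes, wt_anchor_ids)
        venn = anchor_venn(matched, set(classes))
        fate_df = wt_cls.assign(loop_fate=lfate, hm_fate=hfate,
                                cell=lfate.str.cat(hfate, sep="/"))
        fate_path = out / "loop_fates_wt.tsv"
        pio.write_table(fate_df, fate_path)
        compare_json = {
            "cells": cells["count"].to_dict(),
            "cell_proportions": cells["proportion"].round(6).to_dict(),
            "association": assoc,
            "n_disappeared": len(matched["disappeared"]),
            "n_maintained": len(matched["maintained"]),
            "n_new": len(matched["new"]),
            "new_loops": {
                k: v for k, v in new_info.items() if k != "new_nonbait_anchors"
            },
            "anchor_venn": venn,
        }
        compare_path = out / "compare_summary.json"
        with open(compare_path, "w") as fh:
            json.dump(compare_json, fh, indent=2)
        new_anchor_path = out / "new_nonbait_anchors.bed"
        new_anchors = sorted(
            a for s in new_info["new_nonbait_anchors"].values() for a in s
        )
        pio.write_bed([fragments.interval(a) for a in new_anchors], new_anchor_path)
        record(
            "compare",
            {"fates": str(fate_path), "summary": str(compare_path),
             "new_nonbait_anchors": str(new_anchor_path)},
            {"n_disappeared": len(matched["disappeared"]),
             "n_new": len(matched["new"]),
             "chi2_p": assoc["p_value"]},
        )

        # -- stage 5: enrich -------------------------------------------------
        if new_anchors:
            targets = [fragments.interval(a) for a in new_anchors]
        else:
            targets = [fragments.interval(a) for a in bait_anchor_ids]
        space = [
            GenomicInterval(chrom, 0, len(seq)) for chrom, seq in genome.items()
        ]
        tracks = {
            H2AUB_MARK: pio.read_bedgraph(paths["h2aub_wt"]),
            K27_MARK: pio.read_bedgraph(paths["k27_wt"]),
        }
        enr = enrichment_test(tracks, targets, space, seed=seed)
        enr_path = out / "enrichment.tsv"
        pio.write_table(enr, enr_path)
        record(
            "enrich", {"enrichment": str(enr_path)},
            {"n_targets": len(targets),
             "calls": enr.set_index("mark")["call"].to_dict()},
        )

        # -- stage 6: expression ---------------------------------------------
        genes = pio.read_gff3_genes(paths["genes"])
        expr = pio.read_table(paths["expression"]).set_index("gene_id")["expression"]
        de = pio.read_table(paths["de_labels"]).set_index("gene_id")["de_label"]
        groups = bait_region_groups(baits, wt_cls)
        gene_groups = assign_genes_to_regions(groups, fragments, genes)
        props = expression_proportions(gene_groups, expr)
        cell_genes = {
            cell: genes_at_loop_anchors(
                fate_df[fate_df["cell"] == cell], fragments, genes, classes
            )
            for cell in FATE_CELLS
        }
        up = upregulated_fraction_by_fate(
            {k: sorted(v) for k, v in cell_genes.items()}, de
        )
        props_path = out / "expression_proportions.tsv"
        up_path = out / "upregulated_by_fate.tsv"
        pio.write_table(props.reset_index(), props_path)
        pio.write_table(up.reset_index(), up_path)
        record(
            "expression",
            {"proportions": str(props_path), "upregulated": str(up_path)},
            {"n_genes_assigned": len(gene_groups),
             "fraction_up": {k: (None if np.isnan(v) else round(float(v), 4))
                             for k, v in up["fraction_up"].items()}},
        )
    except PipelineError:
        raise
    except Exception as exc:  # halt with a partial manifest
        finish("failed")
        raise PipelineError(f"stage failure: {exc}") from exc

    return finish("complete")
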