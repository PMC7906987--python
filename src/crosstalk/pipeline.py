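"""End-to-end orchestration: preprocess -> per-compartment meta-analysis ->
DEG comparison -> paired-cohort correlation screen -> secretome annotation
-> writers, with a machine-readable run log.

Re-running with identical inputs and seed reproduces identical output files
byte for byte: every stochastic step derives from the config seed, floats
are serialized at fixed precision, and the run log contains no timestamps.
"""

from __future__ import annotations

import json
import os

import pandas as pd

from . import io as cio
from .datatypes import AnalysisConfig, StudyCollection
from .exceptions import DataValidationError, StageError
from .meta import MetaAnalysisResult, export_enrichment_genelist, meta_analyze
from .pairs import (build_network, expected_false_pairs, find_pairs_one_cohort,
                    intersect_pairs, pairs_table)
from .preprocess import drop_incomplete_genes, quantile_normalize
from .secretome import annotate_pairs, load_secretome
from .venn import venn_partition

_FAIL_MARKER = "FAILED.txt"


def preprocess_collection(collection: StudyCollection) -> tuple[StudyCollection, dict]:
    """Quantile-normalize every dataset (within dataset) after dropping genes
    with missing values.  Inputs are expected already on the log2 scale;
    apply ``preprocess.log2_transform`` upstream when they are not.
    """
    out, dropped = [], {}
    for ds in collection.datasets:
        vals, gone = drop_incomplete_genes(ds.values)
        if gone:
            dropped[ds.dataset_id] = gone
        if vals.shape[0] == 0:
            raise DataValidationError(f"{ds.dataset_id}: no complete genes left")
        norm = quantile_normalize(vals)
        out.append(type(ds)(dataset_id=ds.dataset_id, values=norm,
                            compartment=ds.compartment, group=ds.group,
                            patient_id=ds.patient_id).validate())
    return (StudyCollection(datasets=out, paired_cohorts=collection.paired_cohorts),
            {"dropped_incomplete_genes": {k: len(v) for k, v in dropped.items()}})


def run_pipeline(
    collection: StudyCollection,
    config: AnalysisConfig,
    secretome_path=None,
    out_dir=".",
) -> dict:
    """Execute the full analysis and write all result files into ``out_dir``.

    Returns the run log (also written as ``runlog.json``).  Any stage error
    aborts with the stage name and cause, leaving a FAILED.txt marker next
    to whatever partial outputs exist.
    """
    config.validate()
    collection.validate()
    os.makedirs(out_dir, exist_ok=True)
    marker = os.path.join(out_dir, _FAIL_MARKER)
    if os.path.exists(marker):
        os.remove(marker)

    log: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "dataset_ids": [d.dataset_id for d in collection.datasets],
        "paired_cohorts": [list(c) for c in collection.paired_cohorts],
        "stages": {},
    }
    stage = "preprocess"
    try:
        collection, prep_info = preprocess_collection(collection)
        log["stages"]["preprocess"] = prep_info

        stage = "meta_analysis"
        results: dict[str, MetaAnalysisResult] = {}
        deg_sets: dict[str, set] = {}
        for compartment in ("tubule", "glomerulus"):
            datasets = [d for d in collection.by_compartment(compartment) if d.meta_ready]
            res = meta_analyze(datasets, config)
            results[compartment] = res
            deg_sets[compartment] = res.deg_genes()
            table = cio.build_deg_table(res.meta, res.replication, res.calls)
            cio.write_deg_table(table, os.path.join(out_dir, f"deg_table_{compartment}.tsv"))
            lists = export_enrichment_genelist(res.calls, res.meta, config)
            for direction, genes in lists.items():
                cio.write_genelist(genes, os.path.join(
                    out_dir, f"enrichment_{compartment}_{direction}.txt"))
            log["stages"][f"meta_{compartment}"] = {
                "datasets_used": [d.dataset_id for d in datasets],
                "s0_by_dataset": res.s0_by_dataset,
                "n_genes_tested": int(len(res.meta)),
                "n_final_degs": int(len(deg_sets[compartment])),
                "n_enrichment_up": len(lists["up"]),
                "n_enrichment_down": len(lists["down"]),
            }

        stage = "deg_compare"
        part = venn_partition(deg_sets["tubule"], deg_sets["glomerulus"],
                              labels=("tubule", "glomerulus"))
        cio.write_genelist(sorted(part.unique_a), os.path.join(out_dir, "degs_tubule_unique.txt"))
        cio.write_genelist(sorted(part.unique_b),
                           os.path.join(out_dir, "degs_glomerulus_unique.txt"))
        cio.write_genelist(sorted(part.shared), os.path.join(out_dir, "degs_shared.txt"))
        log["stages"]["deg_compare"] = part.counts()

        stage = "crosstalk"
        per_cohort = {}
        n_tests = 0
        have_degs = bool(deg_sets["tubule"]) and bool(deg_sets["glomerulus"])
        for tub_id, glom_id in collection.paired_cohorts:
            if not have_degs:
                break   # empty DEG universe: nothing to screen
            tub, glom = collection.get(tub_id), collection.get(glom_id)
            found = find_pairs_one_cohort(tub, glom, deg_sets["tubule"],
                                          deg_sets["glomerulus"], config)
            per_cohort[f"{tub_id}|{glom_id}"] = found
            n_tests = max(n_tests,
                          len(deg_sets["tubule"] & set(tub.genes))
                          * len(deg_sets["glomerulus"] & set(glom.genes)))
        pairs = intersect_pairs(per_cohort) if per_cohort else []
        if pairs:
            cio.write_pairs_table(pairs_table(pairs),
                                  os.path.join(out_dir, "pairs_consensus.tsv"))
            cio.write_sif_network(pairs, os.path.join(out_dir, "network.sif"),
                                  os.path.join(out_dir, "network_nodes.tsv"))
            net = build_network(pairs)
            hubs = sorted(((n, d) for n, d in net.degree()), key=lambda x: (-x[1], x[0]))
        else:
            hubs = []
        log["stages"]["crosstalk"] = {
            "pairs_per_cohort": {k: len(v) for k, v in per_cohort.items()},
            "n_consensus_pairs": len(pairs),
            "expected_false_pairs_bound": expected_false_pairs(
                n_tests, config, max(1, len(per_cohort))),
            "top_hubs": [[n, int(d)] for n, d in hubs[:10]],
        }

        stage = "secretome"
        if secretome_path is not None and pairs:
            sec = load_secretome(secretome_path)
            annotated, counts = annotate_pairs(pairs, sec)
            cio.write_pairs_table(annotated, os.path.join(out_dir, "pairs_annotated.tsv"))
            log["stages"]["secretome"] = {
                "secretome_size": sec.size,
                "secretome_sha256": sec.sha256,
                "secreted_tubule_genes": counts["tubule"],
                "secreted_glomerulus_genes": counts["glomerulus"],
                "n_pairs_annotated": int(len(annotated)),
            }
    except Exception as err:  # noqa: BLE001 - converted to a stage failure
        with open(marker, "w", encoding="utf-8") as fh:
            fh.write(f"stage: {stage}\ncause: {err}\n")
        raise StageError(stage, err) from err

    with open(os.path.join(out_dir, "runlog.json"), "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return log
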