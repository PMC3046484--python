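"""Configuration-driven end-to-end orchestration with a run manifest.

Stages run in dependency order: simulate → qc → pair → normalize → merge →
global_patterns → corcor → varshare → overlaptest.  A single YAML/dict
config holds per-stage blocks; unknown keys are rejected up front and
referenced input files are checked before any stage executes.  Every output
file is checksummed into a JSON manifest so reruns can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from xspecies import corcor as corcor_mod
from xspecies import global_patterns as gp
from xspecies import io as xio
from xspecies import normalize as norm_mod
from xspecies import synthgen, varshare
from xspecies.containers import (
    ExpressionMatrix,
    MergedMatrix,
    read_annotation,
    write_annotation,
)
from xspecies.pairing import AlignmentParams, build_pairing_map
from xspecies.qc import QCThresholds, filter_arrays

logger = logging.getLogger("xspecies")

STAGE_ORDER = [
    "simulate",
    "qc",
    "pair",
    "normalize",
    "merge",
    "global_patterns",
    "corcor",
    "varshare",
    "overlaptest",
]

_ALLOWED_KEYS = {
    "outdir": None,
    "seed": None,
    "stages": None,
    "simulate": {
        "n_genes", "tissues", "samples_per_tissue_per_species",
        "n_specific_per_tissue", "n_housekeeping", "effect_size", "noise_sd",
        "batch_sd", "species_shift_sd", "probe_len", "probes_per_probeset",
        "probe_divergence", "multi_probeset_fraction", "activation_cv",
        "qc_arrays", "qc_fail_fraction",
    },
    "qc": {"metrics", "thresholds"},
    "pair": {
        "orthologs", "probes_a", "probes_b", "word_size", "gap_open_penalty",
        "gap_extend_penalty", "match_reward", "mismatch_penalty",
        "optimal_assignment",
    },
    "normalize": {"matrix_a", "matrix_b", "annot_a", "annot_b", "mode",
                  "drop_tissues"},
    "merge": {"pairing"},
    "global_patterns": {"n_components", "silhouette_components"},
    "corcor": {"null_reps", "null_mode", "thresholds", "outer"},
    "varshare": {"tissues", "window_size", "top_fraction", "baseline_reps"},
    "overlaptest": {"universe", "k1", "k2", "overlap"},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate_config(config: dict) -> list[str]:
    unknown_top = set(config) - set(_ALLOWED_KEYS)
    if unknown_top:
        raise ValueError(f"unknown config keys: {sorted(unknown_top)}")
    stages = config.get("stages")
    if stages is None:
        raise ValueError("config must list 'stages'")
    if isinstance(stages, dict):
        enabled = [s for s in STAGE_ORDER if stages.get(s, False)]
        unknown = set(stages) - set(STAGE_ORDER)
    else:
        enabled = [s for s in STAGE_ORDER if s in stages]
        unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if not enabled:
        raise ValueError("no stages enabled")
    for stage in STAGE_ORDER:
        block = config.get(stage, {})
        if block is None:
            block = {}
        bad = set(block) - _ALLOWED_KEYS[stage]
        if bad:
            raise ValueError(f"unknown keys in stage {stage!r}: {sorted(bad)}")
    return enabled


def _preflight(config: dict, enabled: list[str], outdir: Path) -> None:
    """Check that every externally referenced input file exists."""
    produced_by_simulate = "simulate" in enabled
    file_keys = {
        "qc": ["metrics"],
        "pair": ["orthologs", "probes_a", "probes_b"],
        "normalize": ["matrix_a", "matrix_b", "annot_a", "annot_b"],
        "merge": ["pairing"],
    }
    for stage, keys in file_keys.items():
        if stage not in enabled:
            continue
        block = config.get(stage) or {}
        for key in keys:
            if key in block:
                p = Path(block[key])
                if not p.exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} input {key!r} not found: {p}"
                    )
            elif not produced_by_simulate and stage != "merge":
                raise ValueError(
                    f"stage {stage!r} needs {key!r} (no simulate stage to provide it)"
                )


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the run manifest.

    The manifest records, per executed stage, its parameters, warnings and
    the sha256 checksum of every file it wrote.  Identical config (and
    seeds) reproduce identical checksums.  A stage failure halts the run;
    the manifest written so far is saved with the failure recorded.
    """
    enabled = _validate_config(config)
    outdir = Path(outdir if outdir is not None else config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    _preflight(config, enabled, outdir)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": [], "status": "ok"}
    state: dict = {}

    try:
        for stage in enabled:
            logger.info("stage %s: start", stage)
            block = dict(config.get(stage) or {})
            outputs, warnings = _run_stage(stage, block, seed, outdir, state)
            manifest["stages"].append(
                {
                    "name": stage,
                    "params": block,
                    "outputs": {str(p): _sha256(Path(p)) for p in outputs},
                    "warnings": warnings,
                }
            )
            logger.info("stage %s: done (%d outputs)", stage, len(outputs))
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.removeHandler(handler)
        handler.close()
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.removeHandler(handler)
    handler.close()
    return manifest


def _run_stage(stage, block, seed, outdir, state) -> tuple[list[Path], list[str]]:
    if stage == "simulate":
        return _stage_simulate(block, seed, outdir, state)
    if stage == "qc":
        return _stage_qc(block, outdir, state)
    if stage == "pair":
        return _stage_pair(block, outdir, state)
    if stage == "normalize":
        return _stage_normalize(block, outdir, state)
    if stage == "merge":
        return _stage_merge(block, outdir, state)
    if stage == "global_patterns":
        return _stage_global(block, outdir, state)
    if stage == "corcor":
        return _stage_corcor(block, seed, outdir, state)
    if stage == "varshare":
        return _stage_varshare(block, seed, outdir, state)
    if stage == "overlaptest":
        return _stage_overlap(block, outdir, state)
    raise AssertionError(stage)


def _stage_simulate(block, seed, outdir, state):
    qc_arrays = int(block.pop("qc_arrays", 100))
    qc_fail = float(block.pop("qc_fail_fraction", 0.2))
    if "tissues" in block:
        block["tissues"] = tuple(block["tissues"])
    design = synthgen.SynthDesign(seed=seed, **block)
    universe = synthgen.generate_universe(design)
    m_a, m_b, annot_a, annot_b = synthgen.generate_expression(design, universe.truth)
    qc_table, qc_labels = synthgen.generate_qc_table(qc_arrays, qc_fail, seed)

    paths = {
        "orthologs": outdir / "orthologs.tsv",
        "probes_a": outdir / "probes_a.fasta",
        "probes_b": outdir / "probes_b.fasta",
        "matrix_a": outdir / "expr_a.tsv",
        "matrix_b": outdir / "expr_b.tsv",
        "annot_a": outdir / "annot_a.tsv",
        "annot_b": outdir / "annot_b.tsv",
        "qc_metrics": outdir / "qc_metrics.tsv",
        "qc_labels": outdir / "qc_labels.tsv",
        "truth_pairs": outdir / "truth_probeset_pairs.tsv",
    }
    xio.write_ortholog_table(universe.ortholog_table, paths["orthologs"])
    xio.write_probe_fasta(universe.probesets_a, paths["probes_a"])
    xio.write_probe_fasta(universe.probesets_b, paths["probes_b"])
    m_a.to_tsv(paths["matrix_a"])
    m_b.to_tsv(paths["matrix_b"])
    write_annotation(annot_a, paths["annot_a"])
    write_annotation(annot_b, paths["annot_b"])
    xio.write_qc_table(qc_table, paths["qc_metrics"])
    qc_labels.to_frame().assign(array_id=qc_table["array_id"]).to_csv(
        paths["qc_labels"], sep="\t", index=False
    )
    truth_df = pd.DataFrame(
        [
            {"gene_a": ga, "gene_b": gb, "probeset_a": pa, "probeset_b": pb}
            for (ga, gb), (pa, pb) in universe.truth.true_probeset_pairs.items()
        ]
    )
    truth_df.to_csv(paths["truth_pairs"], sep="\t", index=False)

    state.update(
        design=design,
        universe=universe,
        matrix_a=m_a,
        matrix_b=m_b,
        annot_a=annot_a,
        annot_b=annot_b,
        files=paths,
    )
    return list(paths.values()), []


def _stage_qc(block, outdir, state):
    metrics_path = block.get("metrics") or state.get("files", {}).get("qc_metrics")
    if metrics_path is None:
        raise ValueError("qc stage needs a metrics table")
    metrics = xio.read_qc_table(metrics_path)
    thresholds = QCThresholds.from_dict(block.get("thresholds") or {})
    passed, report = filter_arrays(metrics, thresholds)
    pass_path = outdir / "qc_pass.txt"
    pass_path.write_text("\n".join(passed) + ("\n" if passed else ""))
    report_path = outdir / "qc_report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    return [pass_path, report_path], []


def _stage_pair(block, outdir, state):
    files = state.get("files", {})
    orth = xio.read_ortholog_table(block.get("orthologs", files.get("orthologs")))
    probes_a = xio.read_probe_fasta(block.get("probes_a", files.get("probes_a")))
    probes_b = xio.read_probe_fasta(block.get("probes_b", files.get("probes_b")))
    param_keys = {
        k: block[k]
        for k in (
            "word_size", "gap_open_penalty", "gap_extend_penalty",
            "match_reward", "mismatch_penalty", "optimal_assignment",
        )
        if k in block
    }
    params = AlignmentParams(**param_keys)
    pairing, unpairable = build_pairing_map(orth, probes_a, probes_b, params)
    pairing_path = outdir / "pairing.tsv"
    xio.write_pairing_table(pairing, pairing_path)
    unpair_path = outdir / "unpairable.tsv"
    unpairable.to_csv(unpair_path, sep="\t", index=False)
    state["pairing"] = pairing
    warnings = (
        [f"{len(unpairable)} gene pairs unpairable"] if len(unpairable) else []
    )
    return [pairing_path, unpair_path], warnings


def _stage_normalize(block, outdir, state):
    files = state.get("files", {})
    mode = block.get("mode", "by_probeset")
    if mode not in ("by_probeset", "by_sample"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    drop = block.get("drop_tissues") or []
    outputs, warnings = [], []
    for side in ("a", "b"):
        key_m, key_s = f"matrix_{side}", f"annot_{side}"
        if key_m in block:
            m = ExpressionMatrix.from_tsv(block[key_m])
            annot = read_annotation(block[key_s])
        else:
            m, annot = state[key_m], state[key_s]
        if drop:
            m, annot = norm_mod.apply_tissue_drop_list(m, annot, drop)
        fn = (
            norm_mod.normalize_by_probeset
            if mode == "by_probeset"
            else norm_mod.normalize_by_sample
        )
        result = fn(m)
        if result.mad_zero:
            warnings.append(
                f"species {side}: {len(result.mad_zero)} MAD-zero vectors flagged"
            )
        norm_path = outdir / f"expr_{side}_norm.tsv"
        result.matrix.to_tsv(norm_path)
        flag_path = outdir / f"expr_{side}_madzero.txt"
        flag_path.write_text(
            "\n".join(result.mad_zero) + ("\n" if result.mad_zero else "")
        )
        annot_path = outdir / f"annot_{side}_kept.tsv"
        write_annotation(annot, annot_path)
        state[f"norm_{side}"] = result.matrix
        state[f"annot_{side}_kept"] = annot
        outputs += [norm_path, flag_path, annot_path]
    state["norm_mode"] = mode
    return outputs, warnings


def _stage_merge(block, outdir, state):
    pairing = state.get("pairing")
    if "pairing" in block:
        pairing = xio.read_pairing_table(block["pairing"])
    if pairing is None:
        raise ValueError("merge stage needs a pairing (run pair or give a path)")
    merged = norm_mod.merge_matrices(
        state["norm_a"], state["norm_b"], pairing,
        state["annot_a_kept"], state["annot_b_kept"],
    )
    merged_path = outdir / "merged.tsv"
    merged.matrix.to_tsv(merged_path)
    annot_path = outdir / "merged_annot.tsv"
    write_annotation(merged.annotation, annot_path)
    state["merged"] = merged
    return [merged_path, annot_path], []


def _stage_global(block, outdir, state):
    merged: MergedMatrix = state["merged"]
    n_comp = block.get("n_components", 10)
    n_comp = min(n_comp, min(merged.matrix.shape))
    result = gp.pca(merged, n_components=n_comp)
    scores_path = outdir / "pca_scores.tsv"
    out_scores = result.scores.copy()
    annot = merged.annotation.set_index("sample_id")
    out_scores["species"] = annot["species"].reindex(out_scores.index)
    out_scores["tissue"] = annot["tissue"].reindex(out_scores.index)
    out_scores.index.name = "sample_id"
    out_scores.to_csv(scores_path, sep="\t")
    var_path = outdir / "pca_variance.tsv"
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(result.variance_fractions))],
            "variance_fraction": result.variance_fractions,
        }
    ).to_csv(var_path, sep="\t", index=False)

    k = block.get("silhouette_components", 3)
    sil_rows = []
    for label in ("tissue", "species"):
        per_group, overall = gp.cluster_separation(
            result.scores, merged.annotation, label, k=k
        )
        sil_rows.append({"grouping": label, "mean_silhouette": overall})
    sil_path = outdir / "silhouette.tsv"
    pd.DataFrame(sil_rows).to_csv(sil_path, sep="\t", index=False)

    outputs = [scores_path, var_path, sil_path]
    warnings = []
    if merged.matrix.scale_tag == "by_probeset":
        tcm = gp.tissue_correlation_matrix(merged)
        order, _ = gp.hierarchical_cluster(tcm)
        cor_path = outdir / "tissue_correlation.tsv"
        out = tcm.values.copy()
        out.index.name = "group"
        out.to_csv(cor_path, sep="\t")
        order_path = outdir / "tissue_order.txt"
        order_path.write_text("\n".join(order) + "\n")
        outputs += [cor_path, order_path]
    else:
        warnings.append("tissue correlation skipped (needs by_probeset normalization)")
    return outputs, warnings


def _stage_corcor(block, seed, outdir, state):
    pairing = state["pairing"]
    outer = block.get("outer", "pearson")
    result = corcor_mod.corcor_all(state["norm_a"], state["norm_b"], pairing, outer)
    cc_path = outdir / "corcor.tsv"
    result.values.to_csv(cc_path, sep="\t", index=False)
    outputs = [cc_path]
    n_reps = int(block.get("null_reps", 0))
    if n_reps > 0:
        null = corcor_mod.corcor_null(
            state["norm_a"], state["norm_b"], pairing,
            n_reps=n_reps, seed=seed,
            mode=block.get("null_mode", "shuffle_within_row"),
            thresholds=tuple(block.get("thresholds", (0.05, 0.1))),
            outer=outer,
        )
        null_path = outdir / "corcor_null_exceedance.tsv"
        null.exceedance.to_csv(null_path, sep="\t", index=False)
        outputs.append(null_path)
    return outputs, []


def _stage_varshare(block, seed, outdir, state):
    pairing = state["pairing"]
    design = state.get("design")
    tissues = block.get("tissues")
    if tissues is None:
        tissues = list(design.tissues) if design is not None else []
    if not tissues:
        raise ValueError("varshare stage needs tissue names")
    n_pairs = len(pairing)
    window = int(block.get("window_size", max(1, n_pairs // 10)))
    config = varshare.WindowConfig(
        window_size=window, top_fraction=float(block.get("top_fraction", 0.1))
    )
    sub_a = ExpressionMatrix(
        state["norm_a"].data.loc[pairing["probeset_a"]], state["norm_a"].scale_tag
    )
    sub_b = ExpressionMatrix(
        state["norm_b"].data.loc[pairing["probeset_b"]], state["norm_b"].scale_tag
    )
    rows = []
    for tissue in tissues:
        ranked_a = varshare.gene_variance_ranking(sub_a, state["annot_a_kept"], tissue)
        ranked_b = varshare.gene_variance_ranking(sub_b, state["annot_b_kept"], tissue)
        shared = varshare.window_shared_fraction(ranked_a, ranked_b, pairing, config)
        for _, r in shared.windows.iterrows():
            rows.append({"tissue": tissue, **r.to_dict()})
    windows_path = outdir / "varshare_windows.tsv"
    pd.DataFrame(rows).to_csv(windows_path, sep="\t", index=False)
    baseline = varshare.randomized_baseline(
        n_pairs, config, n_reps=int(block.get("baseline_reps", 100)), seed=seed
    )
    base_path = outdir / "varshare_baseline.tsv"
    baseline.to_csv(base_path, sep="\t", index=False)
    return [windows_path, base_path], []


def _stage_overlap(block, outdir, state):
    needed = {"universe", "k1", "k2", "overlap"}
    missing = needed - set(block)
    if missing:
        raise ValueError(f"overlaptest stage missing keys: {sorted(missing)}")
    t = varshare.hypergeom_overlap_test(
        int(block["universe"]), int(block["k1"]), int(block["k2"]), int(block["overlap"])
    )
    path = outdir / "overlap_test.json"
    path.write_text(
        json.dumps(
            {"N": t.N, "K": t.K, "n": t.n, "k": t.k, "p_value": t.p_value}, indent=2
        )
    )
    return [path], []
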