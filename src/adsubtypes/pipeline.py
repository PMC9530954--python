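"""End-to-end orchestration: simulate/load -> correct -> subtype -> signatures
-> GSEA -> clinical -> panels, with provenance.

Configuration is a single declarative mapping (YAML on disk): flat keys plus
per-stage blocks, so every threshold lives in one auditable place. All
randomness derives from the one ``seed`` key; rerunning the same config and
seed reproduces every output byte for byte. Each output table carries the run
seed and threshold set in a ``#`` header comment.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from adsubtypes import __version__, clinical, combat, consensus, diffexp, gsea, io
from adsubtypes.cohort import (
    CONTINUOUS_TRAITS,
    CohortConfig,
    generate_cohort,
    holdout_split,
    save_ground_truth,
)
from adsubtypes.errors import ConfigError, PipelineError
from adsubtypes.panels import search_best_panels

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "thresholds": {
        "alpha": 0.05,
        "delta": 0.2,
        "consensus_threshold": 0.8,
        "k_max": 10,
        "top_k_hubs": 10,
    },
    "combat": {"covariate": "condition", "shrink": True},
    "consensus": {"n_resamples": 100, "sample_fraction": 0.8, "base": "kmeans"},
    "signatures": {"mode": "pairwise"},
    "gsea": {"n_permutations": 1000, "weight": 1.0, "metric": "signal_to_noise"},
    "panels": {"holdout_fraction": 0.3, "ridge": False, "positives": "subgroup"},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return cfg


def merge_config(config: dict | None) -> dict:
    """Overlay user configuration on the documented defaults."""
    merged = copy.deepcopy(DEFAULTS)
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def cohort_config_from_block(block: dict, seed: int) -> CohortConfig:
    kwargs = dict(block)
    if "batches" in kwargs:
        kwargs["batches"] = [tuple(b) for b in kwargs["batches"]]
    if "subtype_proportions" in kwargs:
        kwargs["subtype_proportions"] = tuple(kwargs["subtype_proportions"])
    if "batch_scale_range" in kwargs:
        kwargs["batch_scale_range"] = tuple(kwargs["batch_scale_range"])
    kwargs.setdefault("seed", seed)
    try:
        return CohortConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid synthetic block: {exc}") from exc


def _header(cfg: dict) -> list[str]:
    th = cfg["thresholds"]
    return [
        f"adsubtypes {__version__}",
        f"seed={cfg['seed']}",
        "thresholds: "
        + " ".join(f"{k}={v}" for k, v in sorted(th.items())),
    ]


def _write_table(df: pd.DataFrame, path: Path, cfg: dict, index_label=None) -> None:
    with open(path, "w") as fh:
        for line in _header(cfg):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g", index_label=index_label)


def validate_config(cfg: dict) -> None:
    """Fail before any computation if inputs are not specified."""
    has_synth = "synthetic" in cfg
    has_files = "expression" in cfg and "annotation" in cfg
    if not has_synth and not has_files:
        raise ConfigError(
            "configuration needs either a 'synthetic' block or both "
            "'expression' and 'annotation' paths"
        )


def run_pipeline(config: dict | None, outdir) -> dict[str, Any]:
    """Run every stage and write all result tables under ``outdir``.

    Returns a summary dict with the key intermediate objects (corrected
    matrix, selection trace, signatures, hub panels, panel report, and the
    ground truth when the cohort was synthetic).
    """
    cfg = merge_config(config)
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "INCOMPLETE").unlink(missing_ok=True)
    seed = int(cfg["seed"])
    th = cfg["thresholds"]
    summary: dict[str, Any] = {"outdir": outdir}
    stage = "input"
    try:
        truth = None
        if "synthetic" in cfg:
            cc = cohort_config_from_block(cfg["synthetic"] or {}, seed)
            matrix, annot, truth = generate_cohort(cc)
            io.write_expression(matrix, outdir / "expression.tsv", _header(cfg))
            io.write_annotation(annot, outdir / "annotation.tsv", _header(cfg))
            save_ground_truth(truth, outdir / "ground_truth.txt")
        else:
            matrix = io.read_expression(cfg["expression"])
            annot = io.read_annotation(cfg["annotation"])
            annot = annot.loc[matrix.columns]
        summary["n_genes"], summary["n_samples"] = matrix.shape

        stage = "correct"
        check_before = combat.batch_check(matrix, annot)
        corrected, model = combat.correct(
            matrix, annot,
            covariate=cfg["combat"]["covariate"],
            shrink=cfg["combat"]["shrink"],
        )
        check_after = combat.batch_check(corrected, annot)
        io.write_expression(corrected, outdir / "corrected.tsv", _header(cfg))
        _write_table(
            pd.DataFrame(
                {
                    "separation": [check_before.separation, check_after.separation],
                    "n_batches": [check_before.n_batches, check_after.n_batches],
                },
                index=pd.Index(["before", "after"], name="stage"),
            ),
            outdir / "batch_check.tsv",
            cfg,
        )
        summary["batch_separation"] = (check_before.separation, check_after.separation)
        summary["corrected"] = corrected
        summary["annotation"] = annot

        stage = "differential_expression"
        ad = list(annot.index[annot["condition"] == "AD"])
        nd = list(annot.index[annot["condition"] == "ND"])
        de = diffexp.differential_genes(corrected, ad, nd, th["alpha"], th["delta"])
        _write_table(de, outdir / "de_ad_vs_nd.tsv", cfg, index_label="gene_id")
        summary["n_de_ad_vs_nd"] = int(de["significant"].sum())

        stage = "subtype"
        ccfg = cfg["consensus"]
        runs = consensus.consensus_sweep(
            corrected[ad],
            k_max=int(th["k_max"]),
            n_resamples=int(ccfg["n_resamples"]),
            sample_fraction=float(ccfg["sample_fraction"]),
            seed=seed,
            base=ccfg["base"],
        )
        trace = consensus.select_cluster_count(
            runs, float(th["consensus_threshold"]),
            min_cluster_size=int(ccfg.get("min_cluster_size", 2)),
        )
        score_rows = [
            (k, lab, m)
            for k in sorted(trace.scores)
            for lab, m in sorted(trace.scores[k].items())
        ]
        _write_table(
            pd.DataFrame(score_rows, columns=["K", "cluster", "consensus"]).set_index("K"),
            outdir / "consensus_scores.tsv",
            cfg,
        )
        for k, run in runs.items():
            _write_table(
                pd.DataFrame(run.consensus, index=run.sample_ids, columns=run.sample_ids),
                outdir / f"consensus_matrix_K{k}.tsv",
                cfg,
                index_label="sample_id",
            )
        summary["selection"] = trace
        if trace.chosen_k is None:
            override = cfg.get("force_k")
            if override is None:
                raise ConfigError(
                    "no cluster count reaches the consensus threshold; set "
                    "'force_k' to override"
                )
            chosen_k = int(override)
        else:
            chosen_k = trace.chosen_k
        subgroups = consensus.label_assignments(runs[chosen_k])
        annot = annot.copy()
        annot.loc[subgroups.index, "subgroup"] = subgroups
        io.write_annotation(annot, outdir / "subgroups.tsv", _header(cfg))
        summary["chosen_k"] = chosen_k
        summary["subgroups"] = subgroups
        summary["annotation"] = annot

        stage = "signatures"
        signatures = diffexp.subgroup_specific_upregulated(
            corrected, annot, th["alpha"], th["delta"], mode=cfg["signatures"]["mode"]
        )
        vs_nd = diffexp.subgroup_vs_reference(corrected, annot, "ND", th["alpha"], th["delta"])
        sig_rows = [(s, g) for s in sorted(signatures) for g in signatures[s]]
        _write_table(
            pd.DataFrame(sig_rows, columns=["subgroup", "gene_id"]).set_index("subgroup"),
            outdir / "signatures.tsv",
            cfg,
        )
        gmt = io.GeneSetCollection(
            {
                f"subgroup_{s}": io.GeneSet(
                    f"subgroup_{s}", "subgroup-specific upregulated genes",
                    tuple(signatures[s]),
                )
                for s in sorted(signatures)
                if signatures[s]
            }
        )
        io.write_gmt(gmt, outdir / "signatures.gmt")
        _write_table(
            pd.DataFrame(
                {
                    "signature_size": {s: len(signatures[s]) for s in sorted(signatures)},
                    "n_up_vs_nd": {
                        s: int(
                            (vs_nd[s]["significant"] & (vs_nd[s]["mean_diff"] > 0)).sum()
                        )
                        for s in sorted(signatures)
                    },
                }
            ),
            outdir / "signature_counts.tsv",
            cfg,
            index_label="subgroup",
        )
        summary["signatures"] = signatures

        stage = "gsea"
        gcfg = cfg["gsea"]
        members = {
            s: list(annot.index[annot["subgroup"] == s]) for s in sorted(signatures)
        }
        comparisons = {
            f"subgroup_{s}": (members[s], nd, signatures[s])
            for s in sorted(signatures)
            if signatures[s] and len(members[s]) >= 3
        }
        results = gsea.gsea_collection(
            corrected,
            comparisons,
            n_permutations=int(gcfg["n_permutations"]),
            seed=seed + 1,
            metric=gcfg["metric"],
            weight=float(gcfg["weight"]),
        )
        report_rows = []
        hub_panels: dict[str, list[str]] = {}
        hub_rows = []
        for s in sorted(signatures):
            name = f"subgroup_{s}"
            if name not in results:
                continue
            res = results[name]
            ranked = gsea.rank_metric(corrected, members[s], nd, gcfg["metric"])
            hubs = gsea.select_hub_genes(res, ranked, k=int(th["top_k_hubs"]))
            hub_panels[s] = [g for g, _ in hubs]
            hub_rows.extend((s, i + 1, g, sc) for i, (g, sc) in enumerate(hubs))
            report_rows.append(
                (
                    name, res.es, res.nes, res.p_nominal, res.fdr_q,
                    len(res.leading_edge), ",".join(res.leading_edge),
                )
            )
        _write_table(
            pd.DataFrame(
                report_rows,
                columns=["set", "ES", "NES", "p_nominal", "fdr_q", "n_leading_edge", "leading_edge"],
            ).set_index("set"),
            outdir / "gsea_report.tsv",
            cfg,
        )
        _write_table(
            pd.DataFrame(hub_rows, columns=["subgroup", "rank", "gene_id", "metric"]).set_index(
                "subgroup"
            ),
            outdir / "hub_panels.tsv",
            cfg,
        )
        summary["gsea"] = results
        summary["hub_panels"] = hub_panels

        stage = "clinical"
        grouping = pd.Series(pd.NA, index=annot.index, dtype=object)
        grouping[annot["condition"] == "ND"] = "ND"
        has_sub = annot["subgroup"].notna()
        grouping[has_sub] = annot.loc[has_sub, "subgroup"]
        comparisons_t = clinical.compare_traits(annot, grouping, CONTINUOUS_TRAITS)
        if "sex" in annot.columns:
            comparisons_t += clinical.compare_female_proportion(annot, grouping)
        _write_table(
            pd.DataFrame(
                [
                    (c.trait, c.group_a, c.group_b, c.n_a, c.n_b, c.test, c.statistic, c.p, c.stars)
                    for c in comparisons_t
                ],
                columns=["trait", "group_a", "group_b", "n_a", "n_b", "test", "statistic", "p", "stars"],
            ).set_index("trait"),
            outdir / "trait_comparisons.tsv",
            cfg,
        )
        _write_table(
            clinical.trait_spearman_matrix(annot, CONTINUOUS_TRAITS),
            outdir / "trait_spearman.tsv",
            cfg,
            index_label="trait",
        )
        hub_trait = []
        for s, genes in sorted(hub_panels.items()):
            ids = members[s]
            tbl = clinical.trait_correlation_table(
                corrected.loc[genes, ids], annot, CONTINUOUS_TRAITS
            ).reset_index()
            tbl.insert(0, "subgroup", s)
            hub_trait.append(tbl)
        if hub_trait:
            _write_table(
                pd.concat(hub_trait, ignore_index=True).set_index("subgroup"),
                outdir / "hub_trait_correlation.tsv",
                cfg,
            )
        eig_rows = []
        ad_ids = list(annot.index[annot["condition"] == "AD"])
        for s in sorted(signatures):
            if not signatures[s]:
                continue
            profile = clinical.module_eigengene(corrected.loc[signatures[s], ad_ids])
            tbl = clinical.trait_correlation_table(
                profile.scores.to_frame().T.set_axis([f"ME_{s}"]), annot, CONTINUOUS_TRAITS
            ).reset_index()
            tbl.insert(0, "variance_explained", profile.variance_explained)
            eig_rows.append(tbl)
        if eig_rows:
            _write_table(
                pd.concat(eig_rows, ignore_index=True).set_index("feature"),
                outdir / "eigengene_trait.tsv",
                cfg,
            )

        stage = "panels"
        pcfg = cfg["panels"]
        train, val = holdout_split(
            corrected, annot, float(pcfg["holdout_fraction"]), seed + 2
        )
        report = search_best_panels(
            train, val, hub_panels, ridge=bool(pcfg["ridge"]), positives=pcfg["positives"]
        )
        rows = [
            (s, len(e.genes), ",".join(e.genes), e.auc, e.band, e.ridge_fallback, e.error or "")
            for s in sorted(report.evaluations)
            for e in report.evaluations[s]
        ]
        _write_table(
            pd.DataFrame(
                rows, columns=["subgroup", "size", "genes", "auc", "band", "ridge", "error"]
            ).set_index("subgroup"),
            outdir / "panel_search.tsv",
            cfg,
        )
        _write_table(
            pd.DataFrame(
                [
                    (s, ",".join(e.genes), e.auc, e.band)
                    for s, e in sorted(report.best.items())
                ],
                columns=["subgroup", "genes", "auc", "band"],
            ).set_index("subgroup"),
            outdir / "best_panels.tsv",
            cfg,
        )
        summary["panel_report"] = report
        summary["truth"] = truth

        stage = "provenance"
        import scipy
        import sklearn

        provenance = {
            "adsubtypes": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "seed": seed,
            "thresholds": th,
            "config": _jsonable(cfg),
            "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        }
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except PipelineError:
        raise
    except Exception as exc:
        (outdir / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
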