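"""End-to-end orchestration: ingest/simulate → preprocess → score transitions →
call DEGs → Cox screen + AACCV → module extraction → prognosis.

Every stage writes its intermediate table under the output directory; the
run closes with a manifest recording the seed, the configuration and a
SHA-256 hash of every artifact, so reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as mio
from .config import PipelineConfig
from .differential import TransitionSpec, differential_table
from .network import (
    biggest_connected_deg_module,
    load_edge_list,
    merge_networks,
    write_edge_list,
)
from .preprocessing import cyclic_loess_normalize, filter_missing_genes, impute_knn
from .prognosis import km_logrank, pc1_split, stepwise_cox
from .significance import call_degs, fit_score_normal
from .survival import aaccv_curve, combine_bidirectional, compare_transitions, cox_per_gene
from .synthetic import simulate_all

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stages run in order and each failure is re-raised as a
    :class:`PipelineError` naming the stage.  With the same configuration
    (including the seed) all outputs are byte-identical across runs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    def save_expr(expr, name):
        mio.write_expression(expr, out / name)
        files[name] = None

    stage = "inputs"
    try:
        if config.simulation is not None:
            expr, ann, truth, net = simulate_all(config.simulation)
            save_expr(expr, "expr.tsv")
            mio.write_annotation(ann, out / "ann.tsv")
            files["ann.tsv"] = None
            write_edge_list(net, out / "network.tsv")
            files["network.tsv"] = None
            _dump_json(
                {
                    "planted_up": sorted(truth.planted_up),
                    "planted_down": sorted(truth.planted_down),
                    "planted_module": sorted(truth.planted_module),
                    "per_sample_linear_predictor": {
                        k: truth.per_sample_linear_predictor[k]
                        for k in sorted(truth.per_sample_linear_predictor)
                    },
                },
                out / "truth.json",
            )
            files["truth.json"] = None
        else:
            expr = mio.read_expression(config.expression_path)
            ann = mio.read_annotation(config.annotation_path)
            nets = [load_edge_list(p, _sniff_dialect(p)) for p in config.network_paths]
            net = merge_networks(nets) if nets else None
            truth = None

        stage = "preprocess"
        expr = filter_missing_genes(expr, ann)
        expr = impute_knn(expr, k=config.knn_k)
        expr = cyclic_loess_normalize(
            expr, span=config.loess_span, iterations=config.loess_iterations
        )
        save_expr(expr, "expr.norm.tsv")

        stage = "differential"
        transitions = [TransitionSpec(*t) for t in config.transitions]
        diffs = {}
        for t in transitions:
            d = differential_table(expr, ann, t)
            diffs[t.label] = d
            name = f"diff_{t.label}.tsv"
            d.to_csv(out / name, sep="\t", index_label="gene_id", float_format="%.10g")
            files[name] = None

        stage = "significance"
        calls = {}
        fits = {}
        for label, d in diffs.items():
            fit = fit_score_normal(d["d_score"].to_numpy())
            fits[label] = fit
            c = call_degs(d["d_score"], fit, alpha=config.alpha)
            calls[label] = c
            name = f"calls_{label}.tsv"
            pd.concat([d, c], axis=1).to_csv(
                out / name, sep="\t", index_label="gene_id", float_format="%.10g"
            )
            files[name] = None
        _dump_json(
            {label: dataclasses.asdict(fit) for label, fit in fits.items()},
            out / "score_fits.json",
        )
        files["score_fits.json"] = None

        stage = "cox_screen"
        cox = cox_per_gene(expr, ann)
        cox.to_csv(out / "cox.tsv", sep="\t", index_label="gene_id", float_format="%.10g")
        files["cox.tsv"] = None

        stage = "aaccv"
        aaccv = {}
        points_both = {}
        for label, d in diffs.items():
            per_dir = {}
            for direction in ("up", "down"):
                try:
                    pts = aaccv_curve(cox, d, config.top_ns, direction, transition=label)
                except ValueError as err:
                    logger.warning("aaccv %s %s skipped: %s", label, direction, err)
                    continue
                per_dir[direction] = [
                    {"top_n": p.top_n, "aaccv": p.aaccv, "n_skipped": p.n_skipped}
                    for p in pts
                ]
                per_dir.setdefault("_points", {})[direction] = pts
            pts_dir = per_dir.pop("_points", {})
            if "up" in pts_dir and "down" in pts_dir:
                points_both[label] = [
                    combine_bidirectional(u, dn)
                    for u, dn in zip(pts_dir["up"], pts_dir["down"])
                ]
            aaccv[label] = per_dir
        comparisons = []
        labels = [l for l in aaccv if l in points_both]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                for pa, pb in zip(points_both[labels[i]], points_both[labels[j]]):
                    stat, p = compare_transitions(pa, pb)
                    comparisons.append(
                        {
                            "a": labels[i],
                            "b": labels[j],
                            "top_n": pa.top_n,
                            "statistic": stat,
                            "p": p,
                        }
                    )
        _dump_json({"curves": aaccv, "comparisons": comparisons}, out / "aaccv.json")
        files["aaccv.json"] = None

        stage = "network_module"
        module_genes = []
        mt = TransitionSpec(*config.module_transition[:2])
        if net is not None and mt.label in calls:
            degs = set(calls[mt.label].index[calls[mt.label]["significant"]])
            module_genes = sorted(biggest_connected_deg_module(net, degs))
        (out / "module_genes.txt").write_text("".join(g + "\n" for g in module_genes))
        files["module_genes.txt"] = None

        stage = "prognosis"
        prognosis_payload = {"module_size": len(module_genes)}
        if len(module_genes) >= 2:
            cancer = ann[ann["group"] != "normal"]
            res = pc1_split(expr[cancer.index.intersection(expr.columns)], module_genes)
            km = km_logrank(ann, res.group)
            table = stepwise_cox(
                ann, res.group, covariates=("age", "sex", "stage"),
                alpha_enter=config.alpha_enter, pc1=res.pc1,
            )
            prognosis_payload.update(
                {
                    "pc1": {k: float(v) for k, v in res.pc1.items()},
                    "group": {k: str(v) for k, v in res.group.items()},
                    "logrank_chi2": km.logrank_chi2,
                    "logrank_p": km.logrank_p,
                    "cox_table": [dataclasses.asdict(r) for r in table],
                }
            )
            km_rows = []
            for lab, curve in sorted(km.km_curves.items()):
                for _, row in curve.iterrows():
                    km_rows.append((lab, float(row["time"]), float(row["survival"])))
            with open(out / "km_curves.tsv", "w") as fh:
                fh.write("group\ttime\tsurvival\n")
                for lab, t_, s_ in km_rows:
                    fh.write(f"{lab}\t{t_:.10g}\t{s_:.10g}\n")
            files["km_curves.tsv"] = None
        else:
            logger.warning("module too small for prognosis stage (%d genes)", len(module_genes))
        _dump_json(prognosis_payload, out / "prognosis.json")
        files["prognosis.json"] = None

    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, err) from err

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "files": {name: _sha256(out / name) for name in sorted(files)},
    }
    _dump_json(manifest, out / "manifest.json")
    return manifest


def _sniff_dialect(path) -> str:
    return "sif" if str(path).lower().endswith(".sif") else "tsv2col"
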