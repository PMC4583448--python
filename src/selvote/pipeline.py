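"""End-to-end workflow: simulate/load -> normalize -> vote -> consensus -> score.

:func:`run_all` executes the eight study configurations (four base-classifier
kinds, each as a pairwise voting ensemble and as a traditional single
classifier on all markers), writes per-variant proclivity tables, consensus
matrices and heatmaps, a metrics JSON, the cross-variant mismatch
intersection, and a run manifest sufficient to re-execute bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import consensus_map, export_heatmap, persistent_sets
from .ensemble import SVAConfig, run_sva
from .evaluation import run_traditional, summarize_sva
from .io import BiomarkerTable, log_normalize, read_table, write_table
from .simulate import CohortSpec, GroupMoments, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_CLASSIFIERS = ("lda", "qda", "nb", "svm")


def _package_version() -> str:
    try:
        return version("selvote")
    except PackageNotFoundError:
        return "unknown"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_proclivity(result, labels, path: Path) -> None:
    pd.DataFrame({
        "sample_id": result.sample_ids,
        "clinical_label": labels,
        "g_votes": result.g_votes,
        "p_votes": result.p_votes,
        "aggregate_label": result.aggregate_labels,
    }).to_csv(path, index=False)


def _write_ensembles(result, psets, path: Path) -> None:
    g_lists, p_lists = psets.as_pair_lists()
    payload = {
        sid: {
            "gingivitis": [list(p) for p in g_lists[k]],
            "periodontitis": [list(p) for p in p_lists[k]],
        }
        for k, sid in enumerate(result.sample_ids)
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _cohort_from_config(config: dict, out: Path):
    if "input" in config:
        table = read_table(config["input"])
        annotations = None
        cohort_path = Path(config["input"])
    else:
        sim = dict(config.get("simulate", {}))
        moments = GroupMoments(**sim.pop("moments")) if "moments" in sim else GroupMoments()
        spec = CohortSpec(moments=moments, seed=int(config.get("seed", 0)), **sim)
        table, annotations = generate_cohort(spec)
        cohort_path = out / "cohort.csv"
        write_table(table, cohort_path)
        annotations.to_csv(out / "truth.csv", index=False)
    return table, annotations, cohort_path


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Run every configuration described by ``config`` into ``out_dir``.

    Config keys: ``input`` (path) or ``simulate`` (CohortSpec kwargs);
    ``nb`` (realizations, default 1000), ``fold_size`` (default 10),
    ``seed`` (default 0), ``classifiers`` (default all four).
    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    nb = int(config.get("nb", 1000))
    fold_size = int(config.get("fold_size", 10))
    seed = int(config.get("seed", 0))
    kinds = list(config.get("classifiers", DEFAULT_CLASSIFIERS))

    stage = "cohort"
    outputs: dict[str, str] = {}
    metrics: dict = {"sva": {}, "traditional": {}}
    try:
        table, annotations, cohort_path = _cohort_from_config(config, out)
        outputs["cohort"] = str(cohort_path)

        stage = "normalize"
        norm = table if table.normalized else log_normalize(table)
        write_table(norm, out / "normalized.csv")
        outputs["normalized"] = str(out / "normalized.csv")

        # one child seed per (kind, mode), drawn in fixed order
        master = np.random.default_rng(seed)
        child = {(kind, mode): int(master.integers(2**31))
                 for kind in kinds for mode in ("sva", "traditional")}

        mismatch_sets = []
        for kind in kinds:
            stage = f"sva-{kind}"
            cfg = SVAConfig(n_realizations=nb, fold_size=fold_size,
                            classifier=kind, seed=child[(kind, "sva")])
            result = run_sva(norm, cfg)
            _write_proclivity(result, norm.labels, out / f"proclivity_{kind}.csv")
            psets = persistent_sets(result)
            _write_ensembles(result, psets, out / f"ensembles_{kind}.json")
            cmap = consensus_map(psets, norm.labels, norm.sample_ids)
            export_heatmap(cmap, out / f"heatmap_{kind}.png", out / f"tau_{kind}.tsv")
            summary = summarize_sva(result, norm.labels)
            metrics["sva"][kind] = summary.as_dict()
            mismatch_sets.append(set(summary.mismatch_ids))
            for suffix in (f"proclivity_{kind}.csv", f"ensembles_{kind}.json",
                           f"heatmap_{kind}.png", f"tau_{kind}.tsv"):
                outputs[suffix] = str(out / suffix)

            stage = f"traditional-{kind}"
            tcfg = SVAConfig(n_realizations=nb, fold_size=fold_size,
                             classifier=kind, seed=child[(kind, "traditional")])
            metrics["traditional"][kind] = run_traditional(norm, tcfg).as_dict()

        stage = "metrics"
        intersection = sorted(set.intersection(*mismatch_sets)) if mismatch_sets else []
        metrics["mismatch_intersection"] = intersection
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
        outputs["metrics"] = str(out / "metrics.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config,
        "seed": seed,
        "package_version": _package_version(),
        "input_sha256": _sha256(Path(cohort_path)),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
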