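"""End-to-end orchestration: ensemble → reports → indicators → overlaps.

A run is fully specified by (input table, scheme, number of networks,
training config, master seed); the manifest written with every report bundle
records exactly those, so any bundle can be regenerated bit-for-bit. The
master seed spawns one child stream per network (``SeedSequence.spawn``), so
individual networks are independently re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assemblages import (
    ClassScheme,
    TechnologyMatrix,
    prevalence,
    read_assemblage_table,
    scheme_from_name,
    write_assemblage_table,
)
from .ensemble import EnsembleResult, confusion_metrics, train_ensemble
from .indicators import (
    compute_delta_records,
    condition_counts,
    cross_class_overlap,
    delta_table,
    extract_indicator_calls,
    indicator_sets,
    indicator_summary,
)
from .training import TrainingConfig


def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:16]


def run_full_analysis(
    data: str | Path | TechnologyMatrix,
    scheme: str | ClassScheme,
    n_networks: int,
    seed: int,
    out_dir: str | Path,
    config: TrainingConfig | None = None,
    n_min: int = 10,
) -> dict:
    """Run the complete pipeline and write a report bundle.

    Stages: stratified-ensemble training, weighted-mean classification with
    confusion metrics, inversion delta extraction, dual-rule significance
    calls, indicator summary and cross-class overlap statistics. Returns a
    dict of the in-memory results; all tables are also written as CSV plus a
    JSON manifest and summary.
    """
    t0 = time.time()
    if isinstance(scheme, str):
        scheme = scheme_from_name(scheme)
    cfg = config or TrainingConfig()
    if isinstance(data, TechnologyMatrix):
        matrix = data
        input_digest = _digest(matrix.presence.tobytes())
        input_name = "<in-memory>"
    else:
        matrix = read_assemblage_table(data)
        input_digest = _digest(Path(data).read_bytes())
        input_name = str(data)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    try:
        stage = "ensemble"
        ens = train_ensemble(matrix, scheme, n_networks, cfg, seed=seed)
        timings[stage] = time.time() - t0

        stage = "classification_reports"
        t1 = time.time()
        report = confusion_metrics(ens.predicted, ens.truth, scheme)
        timings[stage] = time.time() - t1

        stage = "delta_extraction"
        t1 = time.time()
        records = compute_delta_records(ens, matrix)
        calls = extract_indicator_calls(records, matrix, scheme, n_min=n_min)
        timings[stage] = time.time() - t1

        stage = "summaries"
        t1 = time.time()
        summary = indicator_summary(calls, scheme)
        sets_by_class = indicator_sets(calls, scheme)
        overlap = cross_class_overlap(matrix, sets_by_class)
        timings[stage] = time.time() - t1
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (seed={seed}, scheme={scheme.mode}): {exc}"
        ) from exc

    results = {
        "matrix": matrix,
        "scheme": scheme,
        "ensemble": ens,
        "confusion": report,
        "delta_records": records,
        "calls": calls,
        "summary": summary,
        "indicator_sets": sets_by_class,
        "overlap": overlap,
    }
    manifest = {
        "package": "lithicnet",
        "version": __version__,
        "scheme": scheme.mode,
        "n_networks": n_networks,
        "master_seed": seed,
        "seed_scheme": "numpy SeedSequence(master).spawn(n_networks); child i -> network i",
        "weights_normalized": True,
        "n_min": n_min,
        "config": asdict(cfg),
        "config_digest": _digest(cfg.to_yaml().encode()),
        "input": input_name,
        "input_digest": input_digest,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    write_report(results, out, manifest)
    return results


def write_report(results: dict, out_dir: str | Path, manifest: dict | None = None) -> list[Path]:
    """Write the CSV/JSON report bundle for a pipeline run (idempotent)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix: TechnologyMatrix = results["matrix"]
    scheme: ClassScheme = results["scheme"]
    ens: EnsembleResult = results["ensemble"]
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str, index: bool) -> None:
        path = out / name
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, index=index, lineterminator="\n")
        written.append(path)

    _write(results["confusion"].to_frame(), "confusion.csv", index=True)

    probs = pd.DataFrame(ens.weighted_probs,
                         columns=[f"P({c})" for c in scheme.classes])
    probs.insert(0, "assemblage_id", matrix.assemblage_ids)
    probs["true_class"] = ens.truth
    probs["predicted_class"] = ens.predicted
    probs["pct_networks_correct"] = np.round(ens.correct_rate, 2)
    _write(probs, "assemblage_probabilities.csv", index=False)

    for class_name in scheme.classes:
        tab = delta_table(results["delta_records"], results["calls"],
                          class_name, matrix.technologies)
        safe = class_name.replace("&", "and").replace(" ", "_")
        _write(tab, f"indicators_{safe}.csv", index=False)

    _write(results["summary"], "indicator_summary.csv", index=True)
    _write(condition_counts(matrix), "condition_counts.csv", index=False)

    summary_json = {
        "accuracy_pct": round(results["confusion"].accuracy, 2),
        "n_misclassified": int(sum(p != t for p, t in zip(ens.predicted, ens.truth))),
        "misclassified": [
            {"assemblage_id": matrix.assemblage_ids[i], "target": t, "estimate": p}
            for i, (p, t) in enumerate(zip(ens.predicted, ens.truth)) if p != t
        ],
        "indicator_sets": {c: sorted(s) for c, s in results["indicator_sets"].items()},
        "overlap_pct": {k: round(float(v) * 100) for k, v in results["overlap"].items()},
        "prevalence_pct": {t: round(float(f) * 100)
                           for t, f in prevalence(matrix, "ALL").items()},
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary_json, indent=2) + "\n", encoding="utf-8")
    written.append(path)

    if manifest is not None:
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
        written.append(path)

    log = out / "run.log"
    log.write_text(
        "\n".join(
            [
                f"lithicnet {__version__} run",
                f"scheme={scheme.mode} n_networks={ens.n_networks}",
                f"accuracy={results['confusion'].accuracy:.2f}%",
                f"misclassified={summary_json['n_misclassified']}",
                f"files={[p.name for p in written]}",
            ]
        )
        + "\n",
        encoding="utf-8",
    )
    written.append(log)
    return written
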