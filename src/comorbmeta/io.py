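"""Delimited-text and JSON serialisation for every pipeline artifact.

Trial tables are plain CSV (header row, UTF-8, '.' decimal, empty fields for
missing values) and round-trip losslessly: floats are written with
shortest-repr precision, so read-back reproduces the in-memory table
bit-identically.  Coefficient exports and meta-analysis results serialise to
JSON (vectors plus row-major covariance) with a flat CSV summary alongside.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .stage1 import CoefficientExport
from .meta import MetaResult

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "write_manifest",
    "read_manifest",
    "write_exports",
    "read_exports",
    "exports_summary",
    "write_meta_results",
]


def write_trial_table(table: pd.DataFrame, path) -> None:
    # %.17g guarantees float64 values survive the text round trip exactly
    table.to_csv(path, index=False, float_format="%.17g")


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_exports(exports: Iterable[CoefficientExport], path) -> None:
    payload = [e.to_dict() for e in exports]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_exports(path) -> list[CoefficientExport]:
    payload = json.loads(Path(path).read_text())
    return [CoefficientExport.from_dict(d) for d in payload]


def exports_summary(exports: Sequence[CoefficientExport]) -> pd.DataFrame:
    """Flat one-row-per-coefficient view of a batch of exports."""
    rows = []
    for e in exports:
        for j, lbl in enumerate(e.labels):
            rows.append(
                {
                    "trial_id": e.trial_id,
                    "indication": e.indication,
                    "comparison": e.comparison,
                    "analysis": e.spec.family,
                    "extra_covariate": e.spec.extra_covariate or "",
                    "coefficient": lbl,
                    "estimate": e.estimates[j],
                    "se": e.se[j],
                    "n": e.n,
                    "model_family": e.family,
                }
            )
    return pd.DataFrame(rows)


def write_meta_results(results: Sequence[MetaResult], path) -> None:
    payload = []
    for r in results:
        payload.append(
            {
                "indication": r.indication,
                "comparison": r.comparison,
                "labels": list(r.labels),
                "mean": r.mean.tolist(),
                "lower95": r.lower.tolist(),
                "upper95": r.upper.tolist(),
                "effects_model": r.effects_model,
                "k_trials": r.k_trials,
                "scale": r.scale,
                "tau_mean": None if r.tau_mean is None else r.tau_mean.tolist(),
                "diagnostics": r.diagnostics,
                "seed": r.seed,
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
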