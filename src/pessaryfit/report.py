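"""Serialization of analysis reports (JSON + heatmap CSV) and text rendering."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .crossval import (
    LEAVE_TWO_OUT,
    CVReport,
    PredictionRecord,
)
from .grid import VariableKey
from .pls import VIPResult
from .preprocess import code_response


def _heatmap_to_lists(hm: np.ndarray):
    return [
        [None if np.isnan(v) else float(v) for v in row]
        for row in np.atleast_2d(hm)
    ]


def _heatmap_from_lists(rows, scheme: str) -> np.ndarray:
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in rows]
    )
    return arr[0] if scheme != LEAVE_TWO_OUT else arr


def cv_report_to_dict(report: CVReport) -> dict:
    return {
        "type": "cv_report",
        "scheme": report.scheme,
        "k_variables": report.k_variables,
        "selected_keys": [k.column for k in report.selected_keys],
        "participant_ids": report.participant_ids,
        "predictions": [
            {
                "predicted_participant": r.predicted_participant,
                "co_held_out_participant": r.co_held_out_participant,
                "continuous_response": r.continuous_response,
                "call": r.call,
                "truth": r.truth,
                "correct": r.correct,
            }
            for r in report.predictions
        ],
        "tallies": report.tallies,
        "accuracy_fraction": report.accuracy_fraction,
        "percentages": report.percentages(),
        "heatmap": _heatmap_to_lists(report.heatmap),
    }


def vip_result_to_dict(vip: VIPResult) -> dict:
    return {
        "type": "vip_result",
        "model_A": vip.model_A,
        "ranking": [
            {"variable": k.column, "vip": vip.scores[k]} for k in vip.ranking
        ],
        "n_above_1": vip.n_above_1,
        "n_above_1_5": vip.n_above_1_5,
        "n_above_2": vip.n_above_2,
    }


def write_report(report: CVReport | VIPResult, path) -> None:
    """Write a report as JSON; CV reports additionally emit the heatmap CSV.

    The heatmap CSV sits next to the JSON with a ``.heatmap.csv`` suffix:
    rows are the predicted participants, columns the co-held-out
    participants, cells coded +1 (fitting call), -1 (non-fitting call),
    0 (unknown), empty on the diagonal.
    """
    path = Path(path)
    if isinstance(report, CVReport):
        payload = cv_report_to_dict(report)
        hm = np.atleast_2d(report.heatmap)
        if report.scheme == LEAVE_TWO_OUT:
            frame = pd.DataFrame(
                report.heatmap,
                index=report.participant_ids,
                columns=report.participant_ids,
            )
        else:
            frame = pd.DataFrame(
                {"call": hm.ravel()}, index=report.participant_ids
            )
        frame.to_csv(path.with_suffix(".heatmap.csv"), float_format="%g")
    elif isinstance(report, VIPResult):
        payload = vip_result_to_dict(report)
    else:
        raise TypeError(f"cannot serialize report of type {type(report).__name__}")
    path.write_text(json.dumps(payload, indent=2))


def read_report(path) -> CVReport | VIPResult:
    """Read back a report written by :func:`write_report` (exact round-trip)."""
    payload = json.loads(Path(path).read_text())
    kind = payload.get("type")
    if kind == "vip_result":
        scores = {
            VariableKey.from_column(e["variable"]): e["vip"]
            for e in payload["ranking"]
        }
        return VIPResult(
            scores=scores,
            model_A=payload["model_A"],
            ranking=[VariableKey.from_column(e["variable"]) for e in payload["ranking"]],
            n_above_1=payload["n_above_1"],
            n_above_1_5=payload["n_above_1_5"],
            n_above_2=payload["n_above_2"],
        )
    if kind == "cv_report":
        return CVReport(
            scheme=payload["scheme"],
            k_variables=payload["k_variables"],
            selected_keys=[VariableKey.from_column(c) for c in payload["selected_keys"]],
            predictions=[PredictionRecord(**r) for r in payload["predictions"]],
            tallies=payload["tallies"],
            accuracy_fraction=payload["accuracy_fraction"],
            heatmap=_heatmap_from_lists(payload["heatmap"], payload["scheme"]),
            participant_ids=payload["participant_ids"],
        )
    raise ValueError(f"unknown report type: {kind!r}")


def render_heatmap_text(report: CVReport) -> str:
    """Character-grid view of a leave-two-out heatmap.

    ``+`` correct, ``x`` incorrect, ``?`` unknown, ``.`` diagonal.  The coded
    cell values (+1/-1/0) are appended below the grid.
    """
    if report.scheme != LEAVE_TWO_OUT:
        raise ValueError("text heatmap requires a leave-two-out report")
    n = len(report.participant_ids)
    truth_by_id = {
        r.predicted_participant: r.truth for r in report.predictions
    }
    truth_code = code_response(
        [truth_by_id[pid] for pid in report.participant_ids]
    )
    lines = []
    for i in range(n):
        chars = []
        for j in range(n):
            v = report.heatmap[i, j]
            if i == j or np.isnan(v):
                chars.append(".")
            elif v == 0:
                chars.append("?")
            elif v == truth_code[i]:
                chars.append("+")
            else:
                chars.append("x")
        lines.append(" ".join(chars))
    grid = "\n".join(lines)
    values = "\n".join(
        " ".join(
            "." if i == j or np.isnan(report.heatmap[i, j]) else f"{int(report.heatmap[i, j]):+d}"
            for j in range(n)
        )
        for i in range(n)
    )
    return grid + "\n\ncoded values:\n" + values
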