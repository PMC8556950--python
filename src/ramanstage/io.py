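"""Plain-text interchange: wide-CSV spectra, metadata CSV, JSON/CSV reports.

The on-disk spectra format is a wide CSV whose first column is ``wavenumber``
(strictly ascending, cm^-1) and whose remaining columns are spectrum ids.  A
sibling metadata CSV keyed by ``spectrum_id`` carries cell id, class label,
batch and sampling location.  Evaluation reports and band tables are written
as JSON (with explicit predicted/reference orientation) or CSV.
"""

from __future__ import annotations

import csv
import json
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import SpectraSet

if TYPE_CHECKING:  # pragma: no cover
    from .bands import BandAreaTable
    from .classify import EvaluationReport

#: significant digits preserved on disk (>= 12 so round trips hold to 1e-9)
_FLOAT_FORMAT = "%.12g"


def read_spectra_wide(path, metadata_path=None) -> SpectraSet:
    """Read a wide-CSV spectra file, optionally joining a metadata CSV.

    Spectra keep the file's column order; metadata rows are matched on
    ``spectrum_id`` and every metadata id must exist among the spectra.
    Spectra without a metadata row get a null label (prediction-only use).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    if not header or header[0] != "wavenumber":
        raise ValueError(f"{path}: first column must be named 'wavenumber'")
    ids = header[1:]
    if not ids:
        raise ValueError(f"{path}: no spectrum columns")
    if len(set(ids)) != len(ids):
        seen, dupes = set(), set()
        for i in ids:
            (dupes if i in seen else seen).add(i)
        raise ValueError(f"{path}: duplicated spectrum ids: {sorted(dupes)}")

    frame = pd.read_csv(path)
    axis = frame.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(axis) <= 0):
        raise ValueError(f"{path}: wavenumber axis must be strictly ascending")
    matrix = frame.iloc[:, 1:].to_numpy(dtype=float).T  # spectra x channels

    meta = pd.DataFrame({"spectrum_id": ids})
    if metadata_path is not None:
        md = pd.read_csv(metadata_path, dtype={"spectrum_id": str})
        if "spectrum_id" not in md.columns:
            raise ValueError(f"{metadata_path}: missing 'spectrum_id' column")
        missing = set(md["spectrum_id"]) - set(ids)
        if missing:
            raise ValueError(
                f"{metadata_path}: metadata ids absent from spectra: {sorted(missing)}"
            )
        meta = meta.merge(md, on="spectrum_id", how="left")
    return SpectraSet(axis, matrix, meta)


def write_spectra_wide(spectra_set: SpectraSet, path) -> None:
    """Write a SpectraSet as wide CSV with spectrum ids in sorted order.

    Deterministic: two writes of the same set are byte-identical.
    """
    if len(spectra_set) == 0:
        raise ValueError("refusing to write an empty SpectraSet")
    ids = spectra_set.spectrum_ids
    order = np.argsort(ids, kind="stable")
    frame = pd.DataFrame(
        spectra_set.intensities[order].T,
        columns=[str(i) for i in ids[order]],
    )
    frame.insert(0, "wavenumber", spectra_set.wavenumbers)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def write_metadata(spectra_set: SpectraSet, path) -> None:
    """Sibling metadata CSV, rows in sorted spectrum-id order."""
    cols = ["spectrum_id"] + [c for c in spectra_set.meta.columns if c != "spectrum_id"]
    meta = spectra_set.meta[cols].copy()
    meta["spectrum_id"] = meta["spectrum_id"].astype(str)
    meta = meta.sort_values("spectrum_id", kind="stable")
    meta.to_csv(path, index=False, lineterminator="\n")


def _report_to_jsonable(report: "EvaluationReport") -> dict:
    confusion = report.confusion
    return {
        "kind": "evaluation_report",
        "class_order": [str(c) for c in confusion.index],
        "confusion": {
            "orientation": "rows=predicted, columns=reference",
            "predicted": [str(c) for c in confusion.index],
            "reference": [str(c) for c in confusion.columns],
            "counts": confusion.to_numpy().astype(int).tolist(),
        },
        "metrics": {
            "overall_accuracy_pct": report.overall_accuracy,
            "sensitivity_pct": {str(k): v for k, v in report.sensitivity.items()},
            "specificity_pct": {str(k): v for k, v in report.specificity.items()},
        },
        "n_test": int(report.n_test),
        "provenance": report.provenance,
        "software_version": __version__,
    }


def write_report(report, path, format: str = "json") -> None:
    """Write an EvaluationReport or BandAreaTable as JSON or CSV."""
    from .bands import BandAreaTable
    from .classify import EvaluationReport

    if format not in ("json", "csv"):
        raise ValueError(f"unknown report format {format!r}")

    if isinstance(report, EvaluationReport):
        if report.confusion is None or report.confusion.size == 0:
            raise ValueError("report has no confusion matrix")
        if format == "json":
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(_report_to_jsonable(report), fh, sort_keys=True, indent=2)
                fh.write("\n")
        else:
            rows = []
            for cls in report.confusion.index:
                rows.append(
                    {
                        "class": cls,
                        "sensitivity_pct": report.sensitivity[cls],
                        "specificity_pct": report.specificity[cls],
                    }
                )
            frame = pd.DataFrame(rows)
            frame["overall_accuracy_pct"] = report.overall_accuracy
            frame["n_test"] = report.n_test
            frame.to_csv(path, index=False, lineterminator="\n")
        return

    if isinstance(report, BandAreaTable):
        if format == "json":
            payload = {
                "kind": "band_area_table",
                "areas": {
                    "spectrum_id": report.areas.index.astype(str).tolist(),
                    "bands": report.areas.columns.tolist(),
                    "values": report.areas.to_numpy().tolist(),
                    "label": report.labels.tolist(),
                },
                "medians": {
                    "group": report.medians.index.tolist(),
                    "bands": report.medians.columns.tolist(),
                    "values": report.medians.to_numpy().tolist(),
                },
                "n_unlabelled": int(report.n_unlabelled),
                "software_version": __version__,
            }
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, sort_keys=True, indent=2)
                fh.write("\n")
        else:
            frame = report.areas.copy()
            frame.insert(0, "label", report.labels.to_numpy())
            frame.index.name = "spectrum_id"
            frame.to_csv(path, float_format=_FLOAT_FORMAT, lineterminator="\n")
        return

    raise TypeError(f"unsupported report type {type(report).__name__}")


def read_report(path) -> "EvaluationReport":
    """Round-trip reader for JSON evaluation reports."""
    from .classify import EvaluationReport

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("kind") != "evaluation_report":
        raise ValueError(f"{path}: not an evaluation report")
    conf = payload["confusion"]
    matrix = pd.DataFrame(
        np.asarray(conf["counts"], dtype=int),
        index=pd.Index(conf["predicted"], name="predicted"),
        columns=pd.Index(conf["reference"], name="reference"),
    )
    metrics = payload["metrics"]
    return EvaluationReport(
        confusion=matrix,
        sensitivity=dict(metrics["sensitivity_pct"]),
        specificity=dict(metrics["specificity_pct"]),
        overall_accuracy=float(metrics["overall_accuracy_pct"]),
        n_test=int(payload["n_test"]),
        provenance=payload.get("provenance", {}),
    )
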