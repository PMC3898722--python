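"""Pipeline output writer.

Writes the expression matrix and score table as TSV, the diagnostics and
association results as a structured JSON report, and a manifest listing
every file with a sha256 content checksum. Reruns on identical inputs
produce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .errors import ValidationError
from .quant import ExpressionMatrix


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _as_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return obj
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(
    scores: pd.DataFrame,
    diagnostics: Sequence,
    associations: dict,
    out_dir: str | Path,
    matrix: ExpressionMatrix | None = None,
    metadata: dict | None = None,
) -> dict:
    """Write all pipeline outputs under ``out_dir``; return the manifest."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}")

    if matrix is not None:
        extra = set(scores.index) - set(matrix.sample_ids)
        if extra:
            raise ValidationError(
                f"score table contains samples absent from the expression "
                f"matrix: {sorted(extra)[:5]}"
            )

    written: list[Path] = []

    if matrix is not None:
        p = out_dir / "expression_matrix.tsv"
        matrix.values.to_csv(p, sep="\t", index_label="sample_id")
        written.append(p)

    p = out_dir / "scores.tsv"
    scores.to_csv(p, sep="\t", index_label="sample_id")
    written.append(p)

    report = {
        "metadata": _as_jsonable(metadata or {}),
        "diagnostics": [_as_jsonable(d) for d in diagnostics],
        **{k: _as_jsonable(v) for k, v in associations.items()},
    }
    p = out_dir / "report.json"
    p.write_text(json.dumps(report, indent=1, sort_keys=True))
    written.append(p)

    manifest = {
        "files": {f.name: _sha256(f) for f in written},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
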