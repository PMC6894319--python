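"""Readers and writers for the pipeline's on-disk formats.

* Force/deflection traces: two-column tab-delimited text
  (``time_s``, ``force_uN`` or ``deflection_um``) with a JSON sidecar
  (``<name>.meta.json``) holding pacing mode/frequency, tissue id, group,
  day, and tissue diameter.
* Images: single-channel TIFF or PNG (8/16-bit or float TIFF).
* Gene panels: delimited text with columns ``gene``, ``class``, then one
  column per sample, plus a sidecar sample→group map; the count section
  of nCounter RCC files (CodeClass,Name,Accession,Count) is also parsed.
* Study manifest: TSV with columns path, kind {trace, image, panel},
  tissue_id, group, day, pacing_hz, diameter_mm.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .genepanel import PanelMatrix
from .mechanics import DataError, ForceTrace

PathLike = Union[str, Path]


def write_trace(trace: ForceTrace, path: PathLike, value_col: str = "force_uN") -> None:
    path = Path(path)
    frame = pd.DataFrame({"time_s": trace.time_s, value_col: trace.force_un})
    frame.to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {k: v for k, v in trace.metadata.items()}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_trace(path: PathLike) -> ForceTrace:
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python")
    if frame.shape[1] < 2:
        raise DataError(f"{path}: expected two columns (time, value)")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ForceTrace(
        time_s=frame.iloc[:, 0].to_numpy(float),
        force_un=frame.iloc[:, 1].to_numpy(float),
        metadata=metadata,
    )


def write_image(image: np.ndarray, path: PathLike) -> None:
    import tifffile
    from imageio.v3 import imwrite

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        arr = np.asarray(image, dtype=float)
        lo, hi = arr.min(), arr.max()
        scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        imwrite(path, (scaled * 65535).astype(np.uint16))


def read_image(path: PathLike) -> np.ndarray:
    from imageio.v3 import imread

    return np.asarray(imread(Path(path)), dtype=float)


def write_panel(pm: PanelMatrix, path: PathLike) -> None:
    path = Path(path)
    out = pm.counts.copy()
    out.insert(0, "class", pm.gene_classes)
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)
    sidecar = {"groups": pm.groups.to_dict()}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_panel(path: PathLike, groups: Optional[dict] = None) -> PanelMatrix:
    """Read a panel table (tabular dialect or RCC-lite)."""
    path = Path(path)
    text = path.read_text()
    if "CodeClass" in text.splitlines()[0] or "<CodeSummary>" in text:
        return _read_rcc_lite(path, groups)
    frame = pd.read_csv(path, sep=None, engine="python")
    if not {"gene", "class"} <= set(frame.columns):
        raise DataError(f"{path}: expected 'gene' and 'class' columns")
    counts = frame.drop(columns=["gene", "class"]).set_axis(frame["gene"], axis=0)
    classes = pd.Series(frame["class"].to_numpy(), index=frame["gene"])
    if groups is None:
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if not meta_path.exists():
            raise DataError(f"{path}: sample->group map required (sidecar missing)")
        groups = json.loads(meta_path.read_text())["groups"]
    return PanelMatrix(counts=counts, gene_classes=classes, groups=pd.Series(groups))


def _read_rcc_lite(path: Path, groups: Optional[dict]) -> PanelMatrix:
    """Parse the count section of an nCounter RCC file: one sample with
    CodeClass,Name,Accession,Count rows.  Housekeeping probes keep their
    class; every other code class maps to endogenous."""
    lines = path.read_text().splitlines()
    rows = []
    in_counts = False
    for line in lines:
        line = line.strip()
        if line.startswith("<CodeSummary>"):
            in_counts = True
            continue
        if line.startswith("</CodeSummary>"):
            break
        if not in_counts or not line or line.startswith("CodeClass"):
            if not in_counts and line.startswith("CodeClass"):
                in_counts = True
            continue
        parts = line.split(",")
        if len(parts) < 4:
            continue
        code_class, name, _accession, count = parts[:4]
        rows.append((name, code_class.lower(), float(count)))
    if not rows:
        raise DataError(f"{path}: no count rows found")
    sample = path.stem
    counts = pd.DataFrame({sample: [r[2] for r in rows]}, index=[r[0] for r in rows])
    classes = pd.Series(
        ["housekeeping" if r[1] == "housekeeping" else "endogenous" for r in rows],
        index=[r[0] for r in rows],
    )
    group_map = groups if groups is not None else {sample: "unknown"}
    return PanelMatrix(counts=counts, gene_classes=classes, groups=pd.Series(group_map))


MANIFEST_COLUMNS = ("path", "kind", "tissue_id", "group", "day", "pacing_hz", "diameter_mm")


def read_manifest(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"manifest missing columns: {sorted(missing)}")
    return frame


def write_manifest(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(Path(path), sep="\t", index=False)
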