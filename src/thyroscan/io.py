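"""File I/O for frames, masks, traces, scores and scan records.

Images travel as 8-bit PNG with a JSON sidecar for pose and spacing; masks
as label PNGs (nodule id = pixel value, gland = 255 in its own file);
structured artifacts (scores, BO traces, scan records) as JSON/JSONL/CSV.
Every writer has a matching reader and write-then-read round-trips to an
equal object.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .orient import BOConfig, BOTrace
from .phantom import USFrame, VirtualProbe


class ArtifactParseError(ValueError):
    """A persisted artifact could not be parsed."""


def _write_png(path: Path, array: np.ndarray) -> None:
    Image.fromarray(array).save(path)


def _read_png(path: Path) -> np.ndarray:
    try:
        return np.asarray(Image.open(path))
    except Exception as exc:  # corrupted or missing file
        raise ArtifactParseError(f"cannot read PNG {path}: {exc}") from exc


def save_frame(frame: USFrame, prefix: str | Path) -> list[Path]:
    """Write ``<prefix>_image.png``, mask PNGs and ``<prefix>_meta.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    p_img = prefix.with_name(prefix.name + "_image.png")
    _write_png(p_img, frame.image)
    paths.append(p_img)
    p_gland = prefix.with_name(prefix.name + "_gland.png")
    _write_png(p_gland, frame.gland_mask.astype(np.uint8) * 255)
    paths.append(p_gland)
    nodule_label = np.zeros(frame.image.shape, dtype=np.uint8)
    for nid, mask in frame.nodule_masks.items():
        nodule_label[mask] = nid
    p_nod = prefix.with_name(prefix.name + "_nodules.png")
    _write_png(p_nod, nodule_label)
    paths.append(p_nod)
    meta = {
        "spacing_mm": frame.spacing_mm,
        "seed": frame.seed,
        "contact": frame.contact,
        "pose": dataclasses.asdict(frame.pose),
        "nodule_ids": sorted(int(k) for k in frame.nodule_masks),
    }
    p_meta = prefix.with_name(prefix.name + "_meta.json")
    p_meta.write_text(json.dumps(meta, indent=1))
    paths.append(p_meta)
    return paths


def load_frame(prefix: str | Path) -> USFrame:
    prefix = Path(prefix)
    image = _read_png(prefix.with_name(prefix.name + "_image.png"))
    gland = _read_png(prefix.with_name(prefix.name + "_gland.png")) > 0
    nodule_label = _read_png(prefix.with_name(prefix.name + "_nodules.png"))
    try:
        meta = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ArtifactParseError(f"cannot parse frame metadata: {exc}") from exc
    masks = {int(i): nodule_label == i for i in meta["nodule_ids"]}
    return USFrame(
        image=image.astype(np.uint8),
        spacing_mm=meta["spacing_mm"],
        gland_mask=gland,
        nodule_masks=masks,
        pose=VirtualProbe(**meta["pose"]),
        seed=meta["seed"],
        contact=meta["contact"],
    )


def save_bo_trace(trace: BOTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(trace.as_dict(), indent=1))
    return path


def load_bo_trace(path: str | Path) -> BOTrace:
    try:
        d = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ArtifactParseError(f"cannot parse BO trace: {exc}") from exc
    cfg = BOConfig(
        budget=d["budget"],
        n_init=d["n_init"],
        lengthscale_deg=d["lengthscale_deg"],
        seed=d["seed"],
    )
    return BOTrace(
        x=np.array(d["x"]),
        y=np.array(d["y"]),
        incumbent=np.array(d["incumbent"]),
        config=cfg,
        best_x=np.array(d["best_x"]),
        best_y=d["best_y"],
    )


def save_score(score_dict: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(score_dict, indent=1))
    return path


def load_score(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ArtifactParseError(f"cannot parse score: {exc}") from exc


# Table layout used by clinical comparison reports
SCORE_TABLE_COLUMNS = [
    "Composition",
    "Echogenicity",
    "Margin",
    "Shape",
    "Echogenic foci",
    "Total",
    "Recommendation",
]


def score_table(scores: list[dict]) -> pd.DataFrame:
    """Per-nodule score rows in the standard comparison-table layout."""
    rows = []
    for sc in scores:
        rows.append(
            {
                "Composition": sc["composition"],
                "Echogenicity": sc["echogenicity"],
                "Margin": sc["margin"],
                "Shape": sc["shape"],
                "Echogenic foci": sc["foci"],
                "Total": sc["total"],
                "Recommendation": sc["recommendation"],
            }
        )
    return pd.DataFrame(rows, columns=SCORE_TABLE_COLUMNS)


def save_scan_record(record, out_dir: str | Path) -> dict[str, Path]:
    """ScanRecord -> ticks CSV + events JSONL + per-nodule JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    ticks = pd.DataFrame(record.ticks)
    paths["ticks"] = out / "ticks.csv"
    ticks.to_csv(paths["ticks"], index=False)
    paths["events"] = out / "events.jsonl"
    with open(paths["events"], "w") as fh:
        for ev in record.events:
            fh.write(json.dumps(ev) + "\n")
    paths["nodules"] = out / "nodules.json"
    paths["nodules"].write_text(json.dumps(record.nodules, indent=1))
    if record.bo_trace is not None:
        paths["bo_trace"] = save_bo_trace(record.bo_trace, out / "bo_trace.json")
    summary = {
        "seed": record.seed,
        "completed": record.completed,
        "n_ticks": len(record.ticks),
        "n_matched_nodules": len(record.nodules),
    }
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=1))
    return paths
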