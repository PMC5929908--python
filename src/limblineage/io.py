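"""Reading and writing lineage annotations.

Two plain-text formats are supported:

* the MaMuT/TrackMate XML dialect (the ``Model/AllSpots/SpotsInFrame/Spot``
  and ``Model/AllTracks/Track/Edge`` subset common to TrackMate v3-era
  exports) — the native export format of multi-view lineaging sessions;
* a flat CSV track table with columns ``id, name, frame, x, y, z,
  parent_id`` plus optional ``label_*`` columns.

Only the annotation XML is handled; the BigDataViewer HDF5/XML image
containers that accompany it in the wild are out of scope.  Unknown XML
elements and attributes are ignored on read and never written, so a
round-trip through this module is lossless only for the subset above
(which is everything the downstream analysis consumes).
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CellDetection, LineageForest, validate_forest

__all__ = [
    "read_mamut_xml",
    "write_mamut_xml",
    "read_tracks_csv",
    "write_tracks_csv",
]

_LABEL_PREFIX = "LABEL_"
_KNOWN_SPOT_ATTRS = {
    "ID",
    "name",
    "FRAME",
    "POSITION_X",
    "POSITION_Y",
    "POSITION_Z",
    "POSITION_T",
}


def _find_model(root: ET.Element) -> ET.Element:
    if root.tag == "Model":
        return root
    model = root.find("Model")
    if model is None:
        raise ValueError("no <Model> element found; not a MaMuT/TrackMate annotation file")
    return model


def read_mamut_xml(path: str | Path) -> LineageForest:
    """Parse a MaMuT/TrackMate annotation XML file into a lineage forest.

    Raises ``ValueError`` on duplicate spot ids, edges referencing missing
    spots, or a spot receiving more than one incoming edge.  A warning is
    emitted when a spot's POSITION_T disagrees with the time derived from
    its frame by more than 1e-3 h (frames are authoritative).
    """
    tree = ET.parse(path)
    root = tree.getroot()
    model = _find_model(root)

    frame_interval = float(root.get("frame_interval_minutes", 7.5))

    detections: dict[int, CellDetection] = {}
    allspots = model.find("AllSpots")
    if allspots is not None:
        for sif in allspots.findall("SpotsInFrame"):
            sif_frame = sif.get("frame")
            for spot in sif.findall("Spot"):
                sid = int(spot.get("ID"))
                if sid in detections:
                    raise ValueError(f"duplicate spot ID {sid}")
                frame = int(spot.get("FRAME", sif_frame))
                pos = (
                    float(spot.get("POSITION_X", 0.0)),
                    float(spot.get("POSITION_Y", 0.0)),
                    float(spot.get("POSITION_Z", 0.0)),
                )
                labels = {
                    k[len(_LABEL_PREFIX):]: v
                    for k, v in spot.attrib.items()
                    if k.startswith(_LABEL_PREFIX)
                }
                t_frame = frame * frame_interval / 60.0
                t_attr = spot.get("POSITION_T")
                if t_attr is not None and abs(float(t_attr) - t_frame) > 1e-3:
                    warnings.warn(
                        f"spot {sid}: POSITION_T={t_attr} inconsistent with frame-derived "
                        f"time {t_frame:.6f} h; using frames",
                        stacklevel=2,
                    )
                detections[sid] = CellDetection(
                    id=sid,
                    frame=frame,
                    position=pos,
                    name=spot.get("name", ""),
                    labels=labels,
                )

    alltracks = model.find("AllTracks")
    if alltracks is not None:
        for track in alltracks.findall("Track"):
            for edge in track.findall("Edge"):
                src = int(edge.get("SPOT_SOURCE_ID"))
                tgt = int(edge.get("SPOT_TARGET_ID"))
                for endpoint in (src, tgt):
                    if endpoint not in detections:
                        raise ValueError(f"edge references missing spot ID {endpoint}")
                if detections[tgt].parent_id is not None and detections[tgt].parent_id != src:
                    raise ValueError(f"spot {tgt} has more than one incoming edge")
                detections[tgt].parent_id = src

    ordered = sorted(detections.values(), key=lambda d: (d.frame, d.id))
    forest = LineageForest(ordered, frame_interval_minutes=frame_interval)
    units = model.get("spatialunits")
    if units:
        forest.metadata["spatialunits"] = units
    return forest


def write_mamut_xml(forest: LineageForest, path: str | Path) -> None:
    """Write a lineage forest as a MaMuT/TrackMate annotation XML file.

    The forest must satisfy the structural invariants; invalid forests are
    refused.  Positions are written with 6 decimal places (micrometres),
    ids and frames as integers, labels as ``LABEL_<key>`` spot attributes.
    """
    report = validate_forest(forest)
    if not report.ok:
        raise ValueError(f"refusing to write invalid forest:\n{report}")

    root = ET.Element("TrackMate", version="1.0")
    root.set("frame_interval_minutes", repr(forest.frame_interval_minutes))
    model = ET.SubElement(
        root, "Model", spatialunits=forest.metadata.get("spatialunits", "µm"), timeunits="h"
    )
    allspots = ET.SubElement(model, "AllSpots", nspots=str(len(forest)))

    by_frame: dict[int, list[CellDetection]] = {}
    for det in forest:
        by_frame.setdefault(det.frame, []).append(det)
    for frame in sorted(by_frame):
        sif = ET.SubElement(allspots, "SpotsInFrame", frame=str(frame))
        for det in sorted(by_frame[frame], key=lambda d: d.id):
            attrs = {
                "ID": str(det.id),
                "name": det.name,
                "FRAME": str(det.frame),
                "POSITION_X": f"{det.position[0]:.6f}",
                "POSITION_Y": f"{det.position[1]:.6f}",
                "POSITION_Z": f"{det.position[2]:.6f}",
                "POSITION_T": f"{det.t_hours:.6f}",
            }
            for k, v in sorted(det.labels.items()):
                attrs[_LABEL_PREFIX + k] = v
            ET.SubElement(sif, "Spot", attrs)

    alltracks = ET.SubElement(model, "AllTracks")
    filtered = ET.SubElement(model, "FilteredTracks")
    for track_id, r in enumerate(forest.roots()):
        edges = [
            (forest.get(i).parent_id, i)
            for i in forest.descendants(r.id)
            if forest.get(i).parent_id is not None
        ]
        if not edges:
            continue
        track = ET.SubElement(
            alltracks, "Track", TRACK_ID=str(track_id), name=r.name or f"Track_{track_id}"
        )
        for src, tgt in sorted(edges, key=lambda e: (forest.get(e[1]).frame, e[1])):
            ET.SubElement(
                track, "Edge", SPOT_SOURCE_ID=str(src), SPOT_TARGET_ID=str(tgt)
            )
        ET.SubElement(filtered, "TrackID", TRACK_ID=str(track_id))

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


_REQUIRED_CSV_COLUMNS = ["id", "frame", "x", "y", "z", "parent_id"]


def read_tracks_csv(path: str | Path, frame_interval_minutes: float = 7.5) -> LineageForest:
    """Read a flat CSV track table into a lineage forest."""
    header = pd.read_csv(path, nrows=0)
    label_dtypes = {c: str for c in header.columns if c.startswith("label_")}
    df = pd.read_csv(path, dtype=label_dtypes)
    missing = [c for c in _REQUIRED_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing required columns: {missing}")
    for col in ("id", "frame"):
        values = df[col]
        if not np.all(values.astype(float) == values.astype(float).round()):
            raise ValueError(f"column {col!r} must be integer-valued")
    label_cols = [c for c in df.columns if c.startswith("label_")]
    detections = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        parent = rec["parent_id"]
        parent_id = None if pd.isna(parent) else int(parent)
        labels = {
            c[len("label_"):]: str(rec[c]) for c in label_cols if not pd.isna(rec[c])
        }
        detections.append(
            CellDetection(
                id=int(rec["id"]),
                frame=int(rec["frame"]),
                position=(float(rec["x"]), float(rec["y"]), float(rec["z"])),
                parent_id=parent_id,
                name="" if "name" not in rec or pd.isna(rec["name"]) else str(rec["name"]),
                labels=labels,
            )
        )
    detections.sort(key=lambda d: (d.frame, d.id))
    return LineageForest(detections, frame_interval_minutes=frame_interval_minutes)


def write_tracks_csv(forest: LineageForest, path: str | Path) -> None:
    """Write a lineage forest as a flat CSV track table (lossless round-trip)."""
    report = validate_forest(forest)
    if not report.ok:
        raise ValueError(f"refusing to write invalid forest:\n{report}")
    label_keys = sorted({k for det in forest for k in det.labels})
    rows = []
    for det in sorted(forest, key=lambda d: (d.frame, d.id)):
        row = {
            "id": det.id,
            "name": det.name,
            "frame": det.frame,
            "x": det.position[0],
            "y": det.position[1],
            "z": det.position[2],
            "parent_id": det.parent_id,
        }
        for k in label_keys:
            row["label_" + k] = det.labels.get(k)
        rows.append(row)
    columns = ["id", "name", "frame", "x", "y", "z", "parent_id"] + [
        "label_" + k for k in label_keys
    ]
    df = pd.DataFrame(rows, columns=columns)
    df["parent_id"] = df["parent_id"].astype("Int64")
    df.to_csv(path, index=False)
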