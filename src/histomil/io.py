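"""Cohort persistence: HDF5 feature container, TSV/CSV tables, manifests.

On-disk cohort layout (written by :func:`write_cohort`):

* ``features.h5`` — one HDF5 group per slide holding ``features`` (n, d),
  ``tile_index``, ``rows``, ``cols``; root attrs record the feature dim.
* ``tiles.tsv``   — per-tile manifest with latent fields when synthetic.
* ``patients.csv``— patient_id, purist_class, the four component scores,
  time, event (plus latent archetype columns for synthetic cohorts).
* ``manifest.csv``— patient_id, slide_id, feature_path, n_tiles.
* ``config.yaml`` — generator config echoed with the resolved seed.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import List, Tuple

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import COMPONENT_NAMES, ComponentScores, PatientRecord, SlideBag
from .exceptions import ConfigurationError, ShapeMismatchError


def config_hash(cfg: dict) -> str:
    """Short stable hash of a config mapping, stamped onto artifacts."""
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_cohort(cohort, outdir) -> Path:
    """Write a generated cohort to ``outdir``; returns the directory path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "features.h5", "w") as f:
        f.attrs["feature_dim"] = cohort.config.feature_dim
        f.create_dataset("directions", data=cohort.directions)
        for bag in cohort.slides:
            g = f.create_group(bag.slide_id)
            g.attrs["patient_id"] = bag.patient_id
            g.create_dataset("features", data=bag.features)
            g.create_dataset("tile_index", data=bag.tile_index)
            if bag.rows is not None:
                g.create_dataset("rows", data=bag.rows)
                g.create_dataset("cols", data=bag.cols)
    cohort.tiles.to_csv(out / "tiles.tsv", sep="\t", index=False)

    prows = []
    for p in cohort.patients:
        row = {"patient_id": p.patient_id, "purist_class": p.purist_class,
               **{name: getattr(p.components, name) for name in COMPONENT_NAMES},
               "time": p.time, "event": p.event}
        if p.archetype is not None:
            row["archetype"] = p.archetype
            row["basal_fraction"] = p.basal_fraction
        prows.append(row)
    pd.DataFrame(prows).to_csv(out / "patients.csv", index=False)

    pd.DataFrame([{"patient_id": b.patient_id, "slide_id": b.slide_id,
                   "feature_path": "features.h5", "n_tiles": b.n_tiles}
                  for b in cohort.slides]).to_csv(out / "manifest.csv",
                                                  index=False)
    cfg = cohort.config.to_dict()
    cfg["config_hash"] = config_hash(cohort.config.to_dict())
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out


def _patients_from_frame(df: pd.DataFrame,
                         slide_map) -> List[PatientRecord]:
    records = []
    for _, r in df.iterrows():
        comps = ComponentScores(*[float(r.get(n, np.nan))
                                  for n in COMPONENT_NAMES]) \
            if all(np.isfinite(r.get(n, np.nan)) for n in COMPONENT_NAMES) \
            else ComponentScores(0, 0, 0, 0)
        records.append(PatientRecord(
            patient_id=str(r["patient_id"]),
            purist_class=str(r.get("purist_class", "classical")),
            components=comps,
            time=float(r.get("time", np.nan)),
            event=int(r.get("event", 0)) if np.isfinite(r.get("event", np.nan)) else 0,
            slide_ids=slide_map.get(str(r["patient_id"]), []),
            archetype=r.get("archetype") if "archetype" in r else None,
            basal_fraction=float(r["basal_fraction"])
            if "basal_fraction" in r and np.isfinite(r["basal_fraction"]) else None))
    return records


def load_cohort(manifest_path) -> Tuple[List[SlideBag], List[PatientRecord]]:
    """Load slide bags + patient records from a cohort manifest.

    Validates slide-id uniqueness, path resolvability and declared tile
    counts against the stored matrices; each failure raises a distinct named
    error identifying the offending slide.
    """
    mpath = Path(manifest_path)
    if mpath.is_dir():
        mpath = mpath / "manifest.csv"
    base = mpath.parent
    man = pd.read_csv(mpath)
    dup = man["slide_id"][man["slide_id"].duplicated()]
    if len(dup):
        raise ConfigurationError(f"duplicate slide_id(s) in manifest: "
                                 f"{sorted(set(dup))}")
    bags: List[SlideBag] = []
    handles = {}
    try:
        for _, r in man.iterrows():
            fpath = base / str(r["feature_path"])
            if not fpath.exists():
                raise FileNotFoundError(
                    f"slide {r['slide_id']}: feature file {fpath} not found")
            if fpath not in handles:
                handles[fpath] = h5py.File(fpath, "r")
            f = handles[fpath]
            sid = str(r["slide_id"])
            if sid not in f:
                raise KeyError(f"slide {sid} missing from {fpath}")
            g = f[sid]
            feats = g["features"][()]
            if feats.shape[0] != int(r["n_tiles"]):
                raise ShapeMismatchError(
                    f"slide {sid}: manifest declares {int(r['n_tiles'])} tiles "
                    f"but matrix has {feats.shape[0]}")
            bags.append(SlideBag(
                slide_id=sid, patient_id=str(r["patient_id"]),
                features=feats,
                tile_index=g["tile_index"][()] if "tile_index" in g else None,
                rows=g["rows"][()] if "rows" in g else None,
                cols=g["cols"][()] if "cols" in g else None))
    finally:
        for f in handles.values():
            f.close()

    slide_map = {}
    for b in bags:
        slide_map.setdefault(b.patient_id, []).append(b.slide_id)
    ppath = base / "patients.csv"
    patients = _patients_from_frame(pd.read_csv(ppath), slide_map) \
        if ppath.exists() else []
    return bags, patients


def load_tiles(cohort_dir) -> pd.DataFrame:
    return pd.read_csv(Path(cohort_dir) / "tiles.tsv", sep="\t")
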