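"""YAML configuration for reporter models and hydraulic networks."""

from __future__ import annotations

from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .errors import DomainError
from .gel import FretGeometry, GelComposition, GelFretModel
from .hydraulics import LeafSegmentation
from .vulnerability import VulnerabilityCurve


def model_to_dict(model: GelFretModel, provenance: dict | None = None) -> dict:
    block = {
        "composition": asdict(model.composition),
        "geometry": asdict(model.geometry),
    }
    if provenance:
        block["calibration"] = provenance
    return {"gel_fret": block}


def model_from_dict(cfg: dict) -> GelFretModel:
    try:
        block = cfg["gel_fret"]
    except KeyError:
        raise DomainError("config has no 'gel_fret' block") from None
    comp = GelComposition(**block.get("composition", {}))
    geom = FretGeometry(**block.get("geometry", {}))
    return GelFretModel(composition=comp, geometry=geom)


def load_model(path) -> GelFretModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def save_model(model: GelFretModel, path, anchor_psi: float | None = None,
               anchor_zeta: float | None = None) -> None:
    """Write a model config; calibrated separation carries provenance."""
    provenance = None
    if model.is_calibrated:
        provenance = {
            "anchor_psi_mpa": anchor_psi,
            "anchor_zeta": anchor_zeta,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
    Path(path).write_text(yaml.safe_dump(model_to_dict(model, provenance), sort_keys=False))


def curve_from_dict(block: dict) -> VulnerabilityCurve:
    return VulnerabilityCurve(**block)


def segmentation_from_dict(block: dict) -> LeafSegmentation:
    if "area_fractions" in block and block["area_fractions"] is not None:
        block = {**block, "area_fractions": tuple(block["area_fractions"])}
    if "site_positions" in block and block["site_positions"] is not None:
        block = {**block, "site_positions": tuple(block["site_positions"])}
    return LeafSegmentation(**block)


def load_hydraulics(path) -> dict:
    """Load a hydraulics config: xylem/outside-xylem curves and segmentation."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    block = cfg.get("hydraulics", cfg)
    out = {}
    if "xylem" in block:
        out["xylem"] = curve_from_dict(block["xylem"])
    if "outside_xylem" in block:
        out["outside_xylem"] = curve_from_dict(block["outside_xylem"])
    if "segmentation" in block:
        out["segmentation"] = segmentation_from_dict(block["segmentation"])
    for key in ("e_rate", "xylem_basis", "anchoring"):
        if key in block:
            out[key] = block[key]
    return out
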