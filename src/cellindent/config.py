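"""YAML run configuration: geometry, materials, load case and solver blocks.

Key names mirror the model's parameter table (cell/nucleus/gel geometry and
moduli); units are fixed to kPa / um / nN / s. Densities are carried for
completeness but unused: body forces other than the applied load are zero
in the quasi-static model.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .geometry import GeometryParams
from .loading import LoadCase, default_materials
from .solver import SolverSettings

__all__ = ["default_config", "load_config", "save_config", "build_from_config"]


def default_config() -> dict:
    return {
        "geometry": {
            "cell_diameter_um": 20.0,
            "nucleus_planar_diameter_um": 6.0,
            "nucleus_vertical_diameter_um": 8.0,
            "gel_radius_um": 225.0,
            "gel_thickness_um": 300.0,
            "contact_disc_diameter_um": 6.0,
            "nucleus_gap_um": 0.5,
            "perimeter_band_width_um": 1.0,
            "resolution": 2,
        },
        "materials": {
            "cytoplasm": {"law": "neo_hookean", "E_kPa": 0.8, "nu": 0.49},
            "nucleus": {"law": "neo_hookean", "E_kPa": 2.0, "nu": 0.49},
            "gel": {"law": "linear_elastic", "E_kPa": 2.4, "nu": 0.48},
            "density_kg_m3": 1000.0,  # carried, unused (zero body force)
            "prony": {
                "G_inf_kPa": 4.05,
                "G_1_kPa": 34.0,
                "G_2_kPa": 20.2,
                "tau_1_s": 0.58,
                "tau_2_s": 5.47,
                "mode": "literal",
            },
        },
        "load": {
            "force_nN": 300.0,
            "config": "top",
            "angle_deg": 50.0,
            "ramp_s": 1.0,
            "hold_s": 60.0,
        },
        "solver": {
            "n_load_steps": 8,
            "newton_tol": 1.0e-8,
            "max_newton_iters": 14,
            "element_order": 2,
            "quadrature": "reduced",
        },
    }


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    base = default_config()
    for section, vals in (cfg or {}).items():
        if isinstance(vals, dict) and section in base:
            base[section].update(vals)
        else:
            base[section] = vals
    return base


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)


def build_from_config(cfg: dict):
    """Translate a config dict into (GeometryParams, materials, LoadCase,
    SolverSettings, resolution)."""
    g = cfg["geometry"]
    params = GeometryParams(
        cell_diameter=g["cell_diameter_um"],
        nucleus_diam_planar=g["nucleus_planar_diameter_um"],
        nucleus_diam_vertical=g["nucleus_vertical_diameter_um"],
        gel_radius=g["gel_radius_um"],
        gel_thickness=g["gel_thickness_um"],
        contact_disc_diameter=g["contact_disc_diameter_um"],
        nucleus_gap=g.get("nucleus_gap_um", 0.5),
        perimeter_band_width=g.get("perimeter_band_width_um", 1.0),
    )
    m = cfg["materials"]
    cyto_law = m["cytoplasm"].get("law", "neo_hookean")
    from .materials import PronyParams

    prony_cfg = m.get("prony", {})
    prony = PronyParams(
        G_inf=prony_cfg.get("G_inf_kPa", 4.05),
        G_1=prony_cfg.get("G_1_kPa", 34.0),
        G_2=prony_cfg.get("G_2_kPa", 20.2),
        tau_1=prony_cfg.get("tau_1_s", 0.58),
        tau_2=prony_cfg.get("tau_2_s", 5.47),
    )
    materials = default_materials(
        E_cyto=m["cytoplasm"]["E_kPa"],
        E_nucleus=m["nucleus"]["E_kPa"],
        nu_cell=m["cytoplasm"].get("nu", 0.49),
        E_gel=m["gel"]["E_kPa"],
        nu_gel=m["gel"].get("nu", 0.48),
        cytoplasm_model=(
            "viscoelastic" if cyto_law == "viscoelastic_prony" else "elastic"
        ),
        prony=prony,
        prony_mode={"literal": "literal", "equilibrium": "equilibrium"}[
            prony_cfg.get("mode", "literal")
        ],
    )
    ld = cfg["load"]
    lc = LoadCase(
        F_normal=ld["force_nN"],
        config=ld["config"],
        angle_deg=ld.get("angle_deg", 50.0),
        ramp_time=ld.get("ramp_s", 1.0),
        hold_time=ld.get("hold_s", 60.0),
    )
    s = cfg["solver"]
    settings = SolverSettings(
        n_load_steps=s.get("n_load_steps", 8),
        newton_tol=s.get("newton_tol", 1e-8),
        max_newton_iters=s.get("max_newton_iters", 14),
        element_order=s.get("element_order", 2),
        quadrature=s.get("quadrature", "reduced"),
        ramp_time=ld.get("ramp_s", 1.0),
        hold_time=ld.get("hold_s", 60.0),
    )
    return params, materials, lc, settings, g.get("resolution", 2)
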