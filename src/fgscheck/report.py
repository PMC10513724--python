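"""Protocol orchestration: run the nine-test characterization over one
configured system and compare systems side by side.

The nine tests, in protocol order:

1. excitation band (peak + FWHM from a spectrometer trace)
2. illumination power density (vendor/power-meter metadata, echoed —
   never measured here)
3. spatial resolution & sharpness (USAF CTF ladder)
4. field-of-view uniformity (band profile)
5. spatial distortion (dot-grid spacings)
6. depth of field (CTF of the 1.0 lp/mm element vs z)
7. concentration sensitivity (well panel, LoD, saturation)
8. imaging depth (well panel, max reliable depth, attenuation fit)
9. signal-to-background ratio (dB, depth wells at 2/3/4 mm)

Tests are independent stages: a failure in one is recorded and the rest
still run, and no cross-test correction (e.g. flat-fielding test 7 with
the test 4 profile) is applied — coupling the stages would change what
each metric means.  Every section of the report carries the parameters it
was computed with, and the provenance block hashes the configuration and
each input file so silent drift is detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .errors import ComparisonError, ConfigError, FgsCheckError
from .field import dot_distances, uniformity_profile
from .io_config import Layout, SystemProfile, load_image, load_layout, load_spectrum
from .resolution import dof_curve, element_rois_from_layout, sharpness_curve
from .spectral import compute_fwhm
from .wells import (
    compute_sbr,
    depth_response,
    detect_floor_and_saturation,
    quantify_wells,
    sbr_wells_from_layout,
)

__all__ = ["SystemReport", "run_protocol", "compare_reports", "SCHEMA_VERSION", "TEST_ORDER"]

SCHEMA_VERSION = 1

#: Protocol order of the nine tests.
TEST_ORDER = (
    "spectrum",
    "power_density",
    "resolution",
    "uniformity",
    "distortion",
    "dof",
    "sensitivity",
    "depth",
    "sbr",
)


def _jsonable(obj: Any) -> Any:
    """Recursively convert results (dataclasses, numpy, tuples) to plain
    JSON-serializable structures."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    return obj


def _sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class SystemReport:
    """Aggregated result of one protocol run.

    ``tests`` maps each test name to a section dict with a ``status`` of
    ``ok`` / ``skipped`` / ``error`` — absent tests are marked skipped
    with a reason, never silently omitted.
    """

    system: dict
    tests: dict
    provenance: dict
    schema_version: int = SCHEMA_VERSION

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": self.schema_version,
                "system": self.system,
                "tests": self.tests,
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SystemReport":
        doc = json.loads(text)
        return cls(
            system=doc["system"],
            tests=doc["tests"],
            provenance=doc["provenance"],
            schema_version=doc["schema_version"],
        )

    def save(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write(self.to_json())

    def summary_row(self) -> dict:
        """Flat key metrics for comparison tables."""
        out: dict[str, Any] = {"system_id": self.system.get("system_id", "?")}

        def _get(test: str, *keys, default=None):
            sec = self.tests.get(test, {})
            if sec.get("status") != "ok":
                return default
            cur = sec.get("result", {})
            for k in keys:
                if cur is None or k not in cur:
                    return default
                cur = cur[k]
            return cur

        out["fwhm_nm"] = _get("spectrum", "fwhm_nm")
        out["peak_nm"] = _get("spectrum", "peak_nm")
        out["power_density_mw_cm2"] = self.system.get("power_density_mw_cm2")
        out["resolving_limit_lp_mm"] = _get("resolution", "resolving_limit_lp_mm")
        out["uniformity_min"] = _get("uniformity", "min_profile")
        out["distortion_index"] = _get("distortion", "distortion_index")
        rng = _get("dof", "in_focus_range_cm")
        out["in_focus_range_cm"] = None if rng is None else tuple(rng)
        out["lod_nm"] = _get("sensitivity", "lod_concentration_nm")
        sat = _get("sensitivity", "saturated_labels")
        out["saturation_onset_nm"] = (
            min(float(s.split()[0]) for s in sat) if sat else None
        )
        out["max_reliable_depth_mm"] = _get("depth", "max_reliable_depth_mm")
        out["panel_sbr_db"] = _get("sbr", "panel_sbr_db")
        return out


def _resolve(base_dir: str, path: str) -> str:
    return path if os.path.isabs(path) else os.path.join(base_dir, path)


def _load_img(entry: Mapping, base_dir: str, files: dict) -> Any:
    path = _resolve(base_dir, entry["image"])
    files[path] = _sha256_file(path)
    return load_image(
        path,
        frame_policy=entry.get("frame_policy", "first_frame"),
        channel_policy=entry.get("channel_policy", "as_is"),
        frame_index=entry.get("frame_index", 0),
        channel_index=entry.get("channel_index"),
    )


def _load_lay(entry: Mapping, base_dir: str, files: dict) -> Layout:
    path = _resolve(base_dir, entry["layout"])
    files[path] = _sha256_file(path)
    return load_layout(path)


def run_protocol(config: str | os.PathLike) -> SystemReport:
    """Execute the configured subset of the nine tests and aggregate one
    report.

    ``config`` is a YAML file with a ``system`` block (vendor metadata,
    including the recorded power density) and a ``tests`` block naming the
    input files per test; relative paths resolve against the config's
    directory.  See the repository examples for a complete configuration.
    """
    config = os.fspath(config)
    try:
        with open(config) as fh:
            doc = yaml.safe_load(fh)
    except Exception as exc:
        raise ConfigError(f"cannot parse config {config}: {exc}") from exc
    if not isinstance(doc, Mapping) or "system" not in doc:
        raise ConfigError("config must be a mapping with a 'system' block")
    sysd = dict(doc["system"])
    profile = SystemProfile(
        system_id=sysd.get("system_id", "unnamed"),
        reported_peak_nm=sysd.get("reported_peak_nm"),
        working_distance_cm=sysd.get("working_distance_cm"),
        fov_cm=tuple(sysd["fov_cm"]) if sysd.get("fov_cm") else None,
        power_density_mw_cm2=sysd.get("power_density_mw_cm2"),
        notes=sysd.get("notes", ""),
    )
    testscfg: Mapping = doc.get("tests", {}) or {}
    base_dir = os.path.dirname(os.path.abspath(config))
    files: dict[str, str] = {}
    sections: dict[str, dict] = {}

    def _run(name: str, fn) -> None:
        entry = testscfg.get(name)
        if entry is None:
            sections[name] = {"status": "skipped", "reason": "not configured"}
            return
        try:
            result, params = fn(entry)
            sections[name] = {"status": "ok", "result": _jsonable(result), "params": params}
        except FgsCheckError as exc:
            sections[name] = {"status": "error", "reason": str(exc)}
        except FileNotFoundError as exc:
            sections[name] = {"status": "skipped", "reason": f"missing input: {exc}"}

    def _t_spectrum(entry):
        path = _resolve(base_dir, entry["trace"])
        files[path] = _sha256_file(path)
        res = compute_fwhm(load_spectrum(path), smooth=entry.get("smooth", False))
        return res, {"smooth": bool(entry.get("smooth", False))}

    def _t_power(entry):
        # Bookkeeping only: power density comes from a power meter, not
        # from image analysis; the report just echoes it.
        value = entry.get("value_mw_cm2", profile.power_density_mw_cm2)
        if value is None:
            raise ConfigError("no power density recorded")
        return {"power_density_mw_cm2": float(value), "measured_by": "power meter"}, {}

    def _t_resolution(entry):
        img = _load_img(entry, base_dir, files)
        layout = _load_lay(entry, base_dir, files)
        thr = float(entry.get("background_threshold", 0.2))
        crit = float(entry.get("criterion_percent", 40.0))
        res = sharpness_curve(img, element_rois_from_layout(layout), thr, crit)
        return res, {"background_threshold": thr, "criterion_percent": crit}

    def _t_uniformity(entry):
        img = _load_img(entry, base_dir, files)
        half = int(entry.get("band_half_width_px", 50))
        masks = []
        if "layout" in entry:
            masks = _load_lay(entry, base_dir, files).rois
        res = uniformity_profile(img, half, masks or None)
        return res, {"band_half_width_px": half, "n_masks": len(masks)}

    def _t_distortion(entry):
        img = _load_img(entry, base_dir, files)
        prom = float(entry.get("min_prominence_frac", 0.2))
        res = dot_distances(img, min_prominence_frac=prom)
        return res, {"min_prominence_frac": prom}

    def _t_dof(entry):
        manifest = _resolve(base_dir, entry["manifest"])
        files[manifest] = _sha256_file(manifest)
        table = pd.read_csv(manifest)
        if not {"z_cm", "path"} <= set(table.columns):
            raise ConfigError("DOF manifest needs columns z_cm, path")
        stack = []
        for _, row in table.iterrows():
            p = _resolve(base_dir, str(row["path"]))
            files[p] = _sha256_file(p)
            stack.append((float(row["z_cm"]), load_image(p)))
        layout = _load_lay(entry, base_dir, files)
        rois = element_rois_from_layout(layout, elements=[(0, 1)])[0]
        thr = float(entry.get("threshold_percent", 60.0))
        res = dof_curve(stack, rois, thr)
        return res, {"threshold_percent": thr}

    def _t_sensitivity(entry):
        img = _load_img(entry, base_dir, files)
        layout = _load_lay(entry, base_dir, files)
        k = float(entry.get("k_sigma", 3.0))
        sf = float(entry.get("sat_frac", 0.99))
        panel = detect_floor_and_saturation(quantify_wells(img, layout.wells), k, sf)
        return panel, {"k_sigma": k, "sat_frac": sf}

    def _t_depth(entry):
        img = _load_img(entry, base_dir, files)
        layout = _load_lay(entry, base_dir, files)
        k = float(entry.get("k_sigma", 3.0))
        panel = quantify_wells(img, layout.wells)
        summary = depth_response(panel, k)
        return {"panel": _jsonable(panel), **_jsonable(summary)}, {"k_sigma": k}

    def _t_sbr(entry):
        img = _load_img(entry, base_dir, files)
        layout = _load_lay(entry, base_dir, files)
        factor = float(entry.get("annulus_factor", 1.5))
        depths = tuple(entry.get("depths_mm", (2.0, 3.0, 4.0)))
        res = compute_sbr(img, sbr_wells_from_layout(layout.wells, depths), factor)
        return res, {"annulus_factor": factor, "depths_mm": list(depths)}

    runners = {
        "spectrum": _t_spectrum,
        "power_density": _t_power,
        "resolution": _t_resolution,
        "uniformity": _t_uniformity,
        "distortion": _t_distortion,
        "dof": _t_dof,
        "sensitivity": _t_sensitivity,
        "depth": _t_depth,
        "sbr": _t_sbr,
    }
    for name in TEST_ORDER:
        _run(name, runners[name])

    config_hash = hashlib.sha256(
        json.dumps(_jsonable(doc), sort_keys=True).encode()
    ).hexdigest()
    provenance = {
        "tool": "fgscheck",
        "tool_version": _pkg_version,
        "config_path": os.path.abspath(config),
        "config_sha256": config_hash,
        "input_sha256": dict(sorted(files.items())),
    }
    return SystemReport(
        system=_jsonable(dataclasses.asdict(profile)), tests=sections, provenance=provenance
    )


def compare_reports(reports: Sequence[SystemReport]) -> pd.DataFrame:
    """Side-by-side key metrics of two or more reports (one column per
    system, one row per metric); skipped tests appear as NA."""
    if len(reports) < 2:
        raise ComparisonError("need at least two reports to compare")
    versions = {r.schema_version for r in reports}
    if len(versions) > 1:
        raise ComparisonError(f"incompatible schema versions: {sorted(versions)}")
    rows = [r.summary_row() for r in reports]
    df = pd.DataFrame(rows).set_index("system_id").T
    df.index.name = "metric"
    return df
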