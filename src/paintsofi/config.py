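"""Declarative run configuration (plain-text YAML) with strict validation.

Unknown keys are rejected; every run writes a fully resolved configuration
snapshot (all defaults filled in) next to its outputs, so a run log always
states the parameters that actually applied.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .blink_sim import KineticParams, OpticsCamera, Phantom, make_filament_phantom, make_grid_phantom, make_point_pair_phantom
from .postproc import SofiConfig

__all__ = ["DEFAULT_CONFIG", "RunConfig", "load_config"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "output_dir": "paintsofi_out",
    "phantom": {
        "kind": "filaments",  # filaments | point_pair | grid
        "n_filaments": 3,
        "extent_nm": [6400.0, 6400.0],
        "site_linear_density_per_nm": 0.04,
        "curvature": 0.5,
        "separation_nm": 180.0,
        "spacing_nm": 100.0,
    },
    # dense, SOFI-optimized kinetics: repeat-motif docking strands, high imager
    # concentration (short dark time), duplex destabilizer (short bright time)
    "kinetics_dense": {
        "per_site_binding_rate": 0.4,
        "mean_bound_time": 0.5,
        "n_repeat_motifs": 5,
        "destabilizer_on_time_factor": 0.2,
        "imager_concentration_nM": 5.0,
    },
    # sparse, SMLM-optimized kinetics: low imager concentration, long dwells
    "kinetics_sparse": {
        "per_site_binding_rate": 0.01,
        "mean_bound_time": 0.5,
        "n_repeat_motifs": 1,
        "destabilizer_on_time_factor": 1.0,
        "imager_concentration_nM": 0.2,
    },
    "optics": {
        "pixel_size": 100.0,
        "psf_fwhm": 300.0,
        "frame_time": 0.01,
        "n_frames": 500,
        "photons_per_bound_imager_per_s": 50000.0,
        "background_photons_per_pixel_per_frame": 10.0,
        "illumination_mode": "TIRF",
        "camera_gain": 2.0,
        "camera_offset": 100.0,
        "read_noise_sd": 1.6,
    },
    "smlm_optics": {
        "frame_time": 0.1,
        "n_frames": 600,
        "background_photons_per_pixel_per_frame": 5.0,
    },
    "sofi": {
        "orders": [2, 3, 4],
        # optical PSF estimate for deconvolution, camera px (matches "optics")
        "psf_fwhm_px": 3.0,
        "deconvolution_iterations": 10,
        "linearize": True,
        "block_length": 1000,
    },
    "smlm": {
        "threshold_factor": 3.0,
        "fit_radius": 4,
        "init_sigma": 1.6,
        "max_uncertainty_nm": 15.0,
        "bin_frames": 500,
        "magnification": 5.0,
    },
    "metrics": {
        "decorrelation": True,
        "jackknife_order": 0,  # 0 disables the (expensive) jackknife SNR map
    },
}


def _merge_strict(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise TypeError(f"configuration key {here} must be a mapping")
            out[key] = _merge_strict(defaults[key], val, here)
        else:
            out[key] = val
    return out


class RunConfig:
    """Resolved configuration; builds the domain objects it describes."""

    def __init__(self, data: dict):
        self.data = _merge_strict(DEFAULT_CONFIG, data or {})

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise TypeError("configuration file must contain a mapping")
        return cls(data)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def kinetics(self, which: str = "dense") -> KineticParams:
        return KineticParams(**self.data[f"kinetics_{which}"])

    def optics(self, mode: str = "sofi", seed: int | None = None) -> OpticsCamera:
        kw = dict(self.data["optics"])
        if mode == "smlm":
            kw.update(self.data["smlm_optics"])
        kw["seed"] = self.seed if seed is None else seed
        return OpticsCamera(**kw)

    def sofi_config(self) -> SofiConfig:
        s = self.data["sofi"]
        return SofiConfig(
            orders=tuple(int(o) for o in s["orders"]),
            psf_fwhm_px=float(s["psf_fwhm_px"]),
            deconvolution_iterations=int(s["deconvolution_iterations"]),
            linearize=bool(s["linearize"]),
            block_length=int(s["block_length"]),
        )

    def build_phantom(self, kinetics: KineticParams | None = None) -> Phantom:
        p = self.data["phantom"]
        kin = kinetics if kinetics is not None else self.kinetics("dense")
        extent = tuple(float(v) for v in p["extent_nm"])
        kind = p["kind"]
        if kind == "filaments":
            return make_filament_phantom(
                int(p["n_filaments"]),
                extent,
                float(p["site_linear_density_per_nm"]),
                kin,
                curvature=float(p["curvature"]),
                seed=self.seed,
            )
        if kind == "point_pair":
            return make_point_pair_phantom(float(p["separation_nm"]), kin, extent)
        if kind == "grid":
            return make_grid_phantom(float(p["spacing_nm"]), extent, kin)
        raise ValueError(f"unknown phantom kind {kind!r}")

    def snapshot(self, path) -> None:
        """Write the fully resolved configuration (all defaults printed)."""
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=False))

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2)


def load_config(path=None) -> RunConfig:
    return RunConfig({}) if path is None else RunConfig.from_file(path)
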