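"""Plain-text configuration for the simulate/benchmark CLI commands.

One ``key = value`` pair per line; ``#`` starts a comment.  Vector values
(shape, scale) are comma-separated, ordered (z, y, x) or (y, x).

Scene keys: shape, scale, n_pairs, scd, n_extra_per_image, background,
noise_sd, zero_bound, seed.  PSF keys: psf_lateral_fwhm, psf_axial_fwhm,
psf_radius_sigmas.
"""

from __future__ import annotations

from pathlib import Path

from .synthetic import PSFModel, SceneConfig, gaussian_psf

__all__ = ["parse_config_text", "load_scene_config"]

_SCENE_DEFAULTS = {
    "n_extra_per_image": 0,
    "background": 0.0,
    "noise_sd": 0.0,
    "zero_bound": False,
    "seed": 0,
}


def parse_config_text(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _parse_bool(s: str) -> bool:
    if s.lower() in ("1", "true", "yes", "on"):
        return True
    if s.lower() in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def load_scene_config(path) -> tuple[SceneConfig, PSFModel]:
    """Read a scene + PSF description from a key=value text file."""
    pairs = parse_config_text(Path(path).read_text())
    required = ("shape", "scale", "n_pairs", "scd", "psf_lateral_fwhm")
    missing = [k for k in required if k not in pairs]
    if missing:
        raise ValueError(f"missing config keys: {', '.join(missing)}")
    shape = tuple(int(v) for v in pairs["shape"].split(","))
    scale = tuple(float(v) for v in pairs["scale"].split(","))
    config = SceneConfig(
        shape=shape,
        scale=scale,
        n_pairs=int(pairs["n_pairs"]),
        scd=float(pairs["scd"]),
        n_extra_per_image=int(
            pairs.get("n_extra_per_image", _SCENE_DEFAULTS["n_extra_per_image"])
        ),
        background=float(pairs.get("background", _SCENE_DEFAULTS["background"])),
        noise_sd=float(pairs.get("noise_sd", _SCENE_DEFAULTS["noise_sd"])),
        zero_bound=_parse_bool(str(pairs.get("zero_bound", "false"))),
        seed=int(pairs.get("seed", _SCENE_DEFAULTS["seed"])),
    )
    lateral = float(pairs["psf_lateral_fwhm"])
    axial = float(pairs["psf_axial_fwhm"]) if "psf_axial_fwhm" in pairs else (
        lateral if len(shape) == 3 else None
    )
    psf = gaussian_psf(
        lateral,
        axial,
        scale,
        radius_sigmas=float(pairs.get("psf_radius_sigmas", 4.0)),
    )
    return config, psf
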