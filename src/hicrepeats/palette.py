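"""Perceptually matched variant palettes.

Variants are embedded into CIE L*a*b* colour space by nonmetric
multidimensional scaling: colour positions are optimized so that the
rank order of pairwise Euclidean Lab distances matches the rank order
of the physicochemical dissimilarities, scored by Kruskal stress-1
(with pool-adjacent-violators isotonic regression supplying the
monotone disparities).  The optimizer is simulated annealing with
random restarts; every proposal outside the sRGB gamut or the
lightness bounds is rejected, so the returned palette is displayable
as-is.  Lightness is floored well above 0 because pure black is
reserved for disrupted repeats in architecture diagrams.

Colorimetry is the standard CIE pipeline (Lab -> XYZ under D65 ->
linear RGB -> sRGB gamma); out-of-gamut conversions are reported,
never silently clamped.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "LabColor",
    "PaletteConfig",
    "PaletteAssignment",
    "lab_to_srgb",
    "srgb_to_lab",
    "in_gamut",
    "nonmetric_stress",
    "fit_palette",
]


class LabColor(NamedTuple):
    L: float
    a: float
    b: float


# sRGB primaries under D65, 2-degree observer; the reference white is
# taken from the matrix itself so that Lab(100, 0, 0) maps to exactly
# (1, 1, 1) in linear RGB.
_RGB_TO_XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)
_XYZ_TO_RGB = np.linalg.inv(_RGB_TO_XYZ)
_XN, _YN, _ZN = _RGB_TO_XYZ @ np.ones(3)

_DELTA = 6.0 / 29.0


def _f_inv(t: float) -> float:
    return t**3 if t > _DELTA else 3 * _DELTA**2 * (t - 4.0 / 29.0)


def _f(t: float) -> float:
    return t ** (1.0 / 3.0) if t > _DELTA**3 else t / (3 * _DELTA**2) + 4.0 / 29.0


def _lab_to_linear_rgb(c: LabColor) -> np.ndarray:
    fy = (c.L + 16.0) / 116.0
    fx = fy + c.a / 500.0
    fz = fy - c.b / 200.0
    xyz = np.array([_XN * _f_inv(fx), _YN * _f_inv(fy), _ZN * _f_inv(fz)])
    return _XYZ_TO_RGB @ xyz


def _gamma(c: float) -> float:
    return 12.92 * c if c <= 0.0031308 else 1.055 * c ** (1 / 2.4) - 0.055


def _gamma_inv(c: float) -> float:
    return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4


def lab_to_srgb(c: LabColor) -> tuple[tuple[float, float, float], str, bool]:
    """CIE Lab -> sRGB.  Returns ((r, g, b) in [0,1], hex, in_gamut).

    When the colour falls outside the gamut the channels are clamped
    for the hex string but the flag reports it, so callers never lose
    that information.
    """
    linear = _lab_to_linear_rgb(c)
    inside = bool((linear >= -1e-9).all() and (linear <= 1 + 1e-9).all())
    clamped = np.clip(linear, 0.0, 1.0)
    srgb = tuple(_gamma(v) for v in clamped)
    hexcode = "#" + "".join(f"{round(v * 255):02X}" for v in srgb)
    return srgb, hexcode, inside


def srgb_to_lab(r: float, g: float, b: float) -> LabColor:
    """Inverse conversion, for round-trip checks and palette I/O."""
    linear = np.array([_gamma_inv(r), _gamma_inv(g), _gamma_inv(b)])
    x, y, z = _RGB_TO_XYZ @ linear
    fx, fy, fz = _f(x / _XN), _f(y / _YN), _f(z / _ZN)
    return LabColor(116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz))


def in_gamut(c: LabColor, tol: float = 1e-6) -> bool:
    """True iff every linear RGB channel lies within [-tol, 1 + tol]."""
    linear = _lab_to_linear_rgb(c)
    return bool((linear >= -tol).all() and (linear <= 1 + tol).all())


def _upper_triangle(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def nonmetric_stress(D: np.ndarray | pd.DataFrame, points: np.ndarray) -> float:
    """Kruskal stress-1 of a Lab configuration against target
    dissimilarities.

    The best monotone nondecreasing transform of the targets is fitted
    to the embedded Euclidean distances by isotonic regression;
    stress-1 = sqrt(sum((dhat - d)^2) / sum(d^2)).
    """
    D = np.asarray(D, dtype=float)
    points = np.asarray(points, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    if points.shape != (n, 3):
        raise ValueError(f"expected {n} Lab points, got shape {points.shape}")
    diff = points[:, None, :] - points[None, :, :]
    embedded = _upper_triangle(np.sqrt((diff**2).sum(axis=-1)))
    targets = _upper_triangle(D)
    denom = (embedded**2).sum()
    if denom == 0:
        return 0.0 if np.allclose(targets, targets[0]) else 1.0
    order = np.argsort(targets, kind="stable")
    iso = IsotonicRegression(increasing=True)
    disparities = np.empty_like(embedded)
    disparities[order] = iso.fit_transform(
        np.arange(len(order)), embedded[order]
    )
    return float(math.sqrt(((disparities - embedded) ** 2).sum() / denom))


@dataclass(frozen=True)
class PaletteConfig:
    seed: int = 0
    n_restarts: int = 8
    iterations: int = 600
    lightness_bounds: tuple[float, float] = (35.0, 90.0)
    ab_bounds: tuple[float, float] = (-110.0, 110.0)
    initial_scale: float = 30.0
    final_scale: float = 2.0
    initial_temperature: float = 0.05
    final_temperature: float = 1e-4

    def __post_init__(self) -> None:
        lo, hi = self.lightness_bounds
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"infeasible lightness bounds ({lo}, {hi})")
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


@dataclass
class PaletteAssignment:
    family_id: str
    colors: dict[int, tuple[LabColor, str]] = field(default_factory=dict)
    stress: float = 0.0
    winner_restart: int = 0

    def hex_of(self, vid: int) -> str:
        return self.colors[vid][1]

    def write_json(self, path: str | Path) -> None:
        payload = {
            "family_id": self.family_id,
            "stress": self.stress,
            "winner_restart": self.winner_restart,
            "colors": {
                str(vid): {"L": lab.L, "a": lab.a, "b": lab.b, "hex": hexcode}
                for vid, (lab, hexcode) in self.colors.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def read_json(cls, path: str | Path) -> "PaletteAssignment":
        payload = json.loads(Path(path).read_text())
        colors = {
            int(vid): (LabColor(c["L"], c["a"], c["b"]), c["hex"])
            for vid, c in payload["colors"].items()
        }
        return cls(
            family_id=payload["family_id"],
            colors=colors,
            stress=payload["stress"],
            winner_restart=payload["winner_restart"],
        )


def _random_in_gamut_point(rng: np.random.Generator, cfg: PaletteConfig) -> np.ndarray:
    lo, hi = cfg.lightness_bounds
    alo, ahi = cfg.ab_bounds
    for _ in range(10_000):
        p = np.array(
            [
                rng.uniform(lo, hi),
                rng.uniform(alo, ahi),
                rng.uniform(alo, ahi),
            ]
        )
        if in_gamut(LabColor(*p)):
            return p
    raise RuntimeError("could not sample an in-gamut colour")  # pragma: no cover


def random_in_gamut_points(
    rng: np.random.Generator, n: int, cfg: PaletteConfig
) -> np.ndarray:
    return np.stack([_random_in_gamut_point(rng, cfg) for _ in range(n)])


def _anneal(
    D: np.ndarray,
    points: np.ndarray,
    rng: np.random.Generator,
    cfg: PaletteConfig,
) -> tuple[np.ndarray, float]:
    lo, hi = cfg.lightness_bounds
    current = points.copy()
    current_stress = nonmetric_stress(D, current)
    best, best_stress = current.copy(), current_stress
    n = len(points)
    for t in range(cfg.iterations):
        frac = t / max(cfg.iterations - 1, 1)
        scale = cfg.initial_scale * (cfg.final_scale / cfg.initial_scale) ** frac
        temp = cfg.initial_temperature * (
            cfg.final_temperature / cfg.initial_temperature
        ) ** frac
        idx = int(rng.integers(n))
        proposal = current[idx] + rng.normal(scale=scale, size=3)
        if not lo <= proposal[0] <= hi or not in_gamut(LabColor(*proposal)):
            continue
        trial = current.copy()
        trial[idx] = proposal
        trial_stress = nonmetric_stress(D, trial)
        delta = trial_stress - current_stress
        if delta <= 0 or rng.random() < math.exp(-delta / temp):
            current, current_stress = trial, trial_stress
            if current_stress < best_stress:
                best, best_stress = current.copy(), current_stress
    return best, best_stress


def fit_palette(
    D: pd.DataFrame,
    cfg: PaletteConfig | None = None,
    family_id: str = "family",
) -> PaletteAssignment:
    """Seeded, gamut-constrained NMDS palette for a variant distance
    matrix (index = variant IDs).

    The best of ``n_restarts`` annealing runs wins (ties broken by the
    lowest restart index); identical seed and input give identical hex
    output.
    """
    if cfg is None:
        cfg = PaletteConfig()
    ids = [int(v) for v in D.index]
    n = len(ids)
    if n == 0:
        raise ValueError("empty distance matrix")
    Dv = np.asarray(D, dtype=float)
    if n == 1:
        rng = cfg.rng("restart:0")
        point = _random_in_gamut_point(rng, cfg)
        best_points, best_stress, winner = point[None, :], 0.0, 0
    else:
        best_points, best_stress, winner = None, math.inf, -1
        for r in range(cfg.n_restarts):
            rng = cfg.rng(f"restart:{r}")
            start = random_in_gamut_points(rng, n, cfg)
            points, stress = _anneal(Dv, start, rng, cfg)
            if stress < best_stress:
                best_points, best_stress, winner = points, stress, r
    colors = {}
    for vid, p in zip(ids, best_points):
        lab = LabColor(*p)
        _, hexcode, inside = lab_to_srgb(lab)
        assert inside, "optimizer emitted an out-of-gamut colour"
        colors[vid] = (lab, hexcode)
    return PaletteAssignment(
        family_id=family_id,
        colors=colors,
        stress=float(best_stress),
        winner_restart=winner,
    )
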