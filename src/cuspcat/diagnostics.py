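"""Cusp-evidence diagnostics and response-surface geometry.

A good cusp fit should place a non-trivial share of observations inside the
bifurcation set (the region of the control plane where two attractors
coexist), show non-normal — bimodal or strongly skewed — behavior there,
and skewed distributions on the single-sheet flanks outside it.  This
module computes that checklist:

* the fraction of observations with a negative Cardan discriminant (the
  working rule asks for roughly 10% or more);
* per-region sample skewness, bimodality coefficient, and the
  model-implied mode count at the region centroid;
* a delay-convention classification of every observation onto the upper or
  lower sheet (or the inaccessible middle region between the attractors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cusp_core import cardan_discriminant, density_modes, equilibria
from .cusp_fit import CuspFitResult, CuspModelSpec, control_coordinates
from .study_data import StandardizedTable

__all__ = [
    "EvidenceThresholds",
    "RegionProfile",
    "CuspEvidenceReport",
    "bifurcation_fraction",
    "classify_sheets",
    "bimodality_coefficient",
    "region_density_profiles",
    "evidence_checklist",
]


@dataclass(frozen=True)
class EvidenceThresholds:
    """Configurable cut-offs for the evidence rules."""

    bifurcation_min_fraction: float = 0.10
    skew_threshold: float = 0.5
    bimodality_threshold: float = 0.555  # uniform-distribution benchmark


@dataclass(frozen=True)
class RegionProfile:
    """Shape summary of the observations falling in one control-plane region."""

    name: str
    n: int
    skewness: float | None
    bimodality: float | None
    mode_count: int | None     # model-implied, at the region's mean control point
    sufficient: bool


@dataclass(frozen=True)
class CuspEvidenceReport:
    """The three-part cusp-evidence checklist plus its inputs."""

    bifurcation_fraction: float
    meets_10pct_rule: bool
    inside_region_nonnormal: bool
    outside_region_skewed: bool
    overall: bool
    region_profiles: tuple[RegionProfile, ...]
    sheet_labels: tuple[str, ...]
    thresholds: EvidenceThresholds = field(default_factory=EvidenceThresholds)

    def to_json(self) -> str:
        return json.dumps(
            {
                "bifurcation_fraction": self.bifurcation_fraction,
                "meets_10pct_rule": self.meets_10pct_rule,
                "inside_region_nonnormal": self.inside_region_nonnormal,
                "outside_region_skewed": self.outside_region_skewed,
                "overall": self.overall,
                "regions": [
                    {
                        "name": r.name, "n": r.n, "skewness": r.skewness,
                        "bimodality": r.bimodality, "mode_count": r.mode_count,
                        "sufficient": r.sufficient,
                    }
                    for r in self.region_profiles
                ],
                "sheet_labels": list(self.sheet_labels),
            },
            indent=2,
        )


def _controls(fit: CuspFitResult, table, spec):
    table = table if table is not None else fit.table
    spec = spec or fit.spec
    return control_coordinates(fit.coefficients, table, spec)


def bifurcation_fraction(fit: CuspFitResult, table: StandardizedTable | None = None,
                         spec: CuspModelSpec | None = None) -> float:
    """Share of observations whose control point lies inside the bifurcation set."""
    alpha, beta, _ = _controls(fit, table, spec)
    delta = 27.0 * alpha ** 2 - 4.0 * beta ** 3
    return float(np.mean(delta < 0))


def classify_sheets(fit: CuspFitResult, table: StandardizedTable | None = None,
                    spec: CuspModelSpec | None = None) -> list[str]:
    """Delay-convention sheet membership per observation.

    Outside the bifurcation set the single attractor defines the sheet
    (upper for a non-negative equilibrium, lower otherwise).  Inside, the
    observation belongs to the nearest stable equilibrium; a state strictly
    nearest the unstable middle root is labelled ``inaccessible``.
    """
    alpha, beta, y = _controls(fit, table, spec)
    labels: list[str] = []
    for a, b, yi in zip(alpha, beta, y):
        eq = equilibria(float(a), float(b))
        dists = [abs(yi - r) for r in eq.roots]
        j = int(np.argmin(dists))
        if len(eq.roots) == 3 and eq.stability[j] == "unstable":
            labels.append("inaccessible")
        elif len(eq.roots) == 1:
            labels.append("upper" if eq.roots[0] >= 0 else "lower")
        else:
            stable = [r for r, s in zip(eq.roots, eq.stability) if s == "stable"]
            nearest = min(stable, key=lambda r: abs(yi - r)) if stable else eq.roots[j]
            labels.append("upper" if nearest >= max(eq.roots) - 1e-12 else "lower")
    return labels


def bimodality_coefficient(x: np.ndarray) -> float | None:
    """Sample bimodality coefficient (g1² + 1) / (g2 + 3(n-1)²/((n-2)(n-3))).

    Values above ~0.555 (the uniform benchmark) suggest bi- or multimodality.
    Returns None for n < 4 where the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return None
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, bias=False)  # excess kurtosis
    return float((g1 ** 2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def _profile(name: str, alpha, beta, y) -> RegionProfile:
    n = y.size
    if n < 3:
        return RegionProfile(name=name, n=int(n), skewness=None, bimodality=None,
                             mode_count=None, sufficient=False)
    skew = float(stats.skew(y, bias=False))  # adjusted Fisher-Pearson
    modes = density_modes(float(np.mean(alpha)), float(np.mean(beta)))
    return RegionProfile(
        name=name, n=int(n), skewness=skew,
        bimodality=bimodality_coefficient(y),
        mode_count=len(modes), sufficient=True,
    )


def region_density_profiles(fit: CuspFitResult, table: StandardizedTable | None = None,
                            spec: CuspModelSpec | None = None,
                            grid: str = "bifurcation") -> list[RegionProfile]:
    """Shape profiles of the observed states by control-plane region.

    ``grid="bifurcation"`` partitions observations into inside/outside the
    bifurcation set; ``grid="3x3"`` tiles the observed (alpha, beta) range
    into nine cells for finer surface profiling.
    """
    alpha, beta, y = _controls(fit, table, spec)
    delta = 27.0 * alpha ** 2 - 4.0 * beta ** 3
    profiles: list[RegionProfile] = []
    if grid == "bifurcation":
        for name, mask in (("inside", delta < 0), ("outside", delta >= 0)):
            profiles.append(_profile(name, alpha[mask], beta[mask], y[mask]))
    elif grid == "3x3":
        a_edges = np.quantile(alpha, [0, 1 / 3, 2 / 3, 1])
        b_edges = np.quantile(beta, [0, 1 / 3, 2 / 3, 1])
        for i in range(3):
            for j in range(3):
                mask = (
                    (alpha >= a_edges[i]) & (alpha <= a_edges[i + 1] + 1e-12)
                    & (beta >= b_edges[j]) & (beta <= b_edges[j + 1] + 1e-12)
                )
                profiles.append(_profile(f"a{i}b{j}", alpha[mask], beta[mask], y[mask]))
    else:
        raise ValueError(f"unknown grid {grid!r}")
    return profiles


def evidence_checklist(fit: CuspFitResult, table: StandardizedTable | None = None,
                       spec: CuspModelSpec | None = None,
                       thresholds: EvidenceThresholds | None = None) -> CuspEvidenceReport:
    """Assemble the three-part cusp-evidence checklist.

    1. At least ~10% of observations inside the bifurcation set.
    2. Non-normal responses inside it: two model-implied modes at the
       inside centroid, or |skewness| or the bimodality coefficient above
       threshold.
    3. Skewed response distribution outside it.
    The overall flag is the conjunction of the three.
    """
    thresholds = thresholds or EvidenceThresholds()
    frac = bifurcation_fraction(fit, table, spec)
    profiles = region_density_profiles(fit, table, spec, grid="bifurcation")
    by_name = {p.name: p for p in profiles}
    inside, outside = by_name["inside"], by_name["outside"]

    meets_10 = frac >= thresholds.bifurcation_min_fraction
    if inside.sufficient:
        inside_nonnormal = bool(
            (inside.mode_count or 0) >= 2
            or abs(inside.skewness) > thresholds.skew_threshold
            or (inside.bimodality is not None
                and inside.bimodality > thresholds.bimodality_threshold)
        )
    else:
        inside_nonnormal = False
    outside_skewed = bool(
        outside.sufficient and abs(outside.skewness) > thresholds.skew_threshold
    )
    return CuspEvidenceReport(
        bifurcation_fraction=frac,
        meets_10pct_rule=meets_10,
        inside_region_nonnormal=inside_nonnormal,
        outside_region_skewed=outside_skewed,
        overall=bool(meets_10 and inside_nonnormal and outside_skewed),
        region_profiles=tuple(profiles),
        sheet_labels=tuple(classify_sheets(fit, table, spec)),
        thresholds=thresholds,
    )
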