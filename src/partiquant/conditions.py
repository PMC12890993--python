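"""Condition parameterisation for the extraction-method experiment.

A *condition* is one tablet-preparation protocol (A-D) or the blank
filtration control.  Each condition is described by the expected particle
load it deposits on a scanned slide: per-morphology particle densities
(particles per mm^2 of analyzable fluid) with log-normal size
distributions, plus an air-bubble rate and whether the preparation tends
to produce dark edge disturbances on the slide.

The default parameter table is chosen so that the qualitative per-bin
ordering reported for the four protocols holds in expectation: protocol A
(no coating removal) is dominated by small dark coating fragments
(<100 um), B (crushing) produces the densest very large (>500 um)
fragments, C the densest mid-range (100-500 um) load, and D (long
boiling) is sparsest in every size class.  The blank control carries only
a trace contamination rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence

import numpy as np
from scipy import stats

MORPHOLOGIES = ("black_dot", "crystal", "cotton")

#: labelled morphine content (mg) of the 60 mg slow-release tablet studied
LABEL_CONTENT_MG = 45.0


@dataclass(frozen=True)
class MorphologySpec:
    """Density and size model for one particle morphology.

    Sizes are maximum caliper (Feret) lengths in micrometres, drawn from a
    log-normal with the given median and geometric standard deviation.
    """

    density_per_mm2: float
    median_um: float
    gsd: float

    def __post_init__(self) -> None:
        if self.density_per_mm2 < 0:
            raise ValueError(f"density must be >= 0, got {self.density_per_mm2}")
        if self.median_um <= 0:
            raise ValueError(f"size median must be > 0, got {self.median_um}")
        if self.gsd < 1:
            raise ValueError(f"geometric SD must be >= 1, got {self.gsd}")

    def size_distribution(self) -> stats.rv_continuous:
        """Frozen log-normal over particle size in micrometres."""
        return stats.lognorm(s=np.log(self.gsd), scale=self.median_um)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: particle load + artifact tendencies."""

    name: str
    morphologies: Mapping[str, MorphologySpec]
    bubble_density_per_mm2: float = 0.3
    edge_artifact: bool = True

    def __post_init__(self) -> None:
        if self.bubble_density_per_mm2 < 0:
            raise ValueError("bubble density must be >= 0")
        unknown = set(self.morphologies) - set(MORPHOLOGIES)
        if unknown:
            raise ValueError(f"unknown morphologies: {sorted(unknown)}")

    @property
    def total_density_per_mm2(self) -> float:
        return sum(m.density_per_mm2 for m in self.morphologies.values())

    def expected_bin_densities(self, edges: Sequence[float] = (100.0, 250.0, 500.0)) -> np.ndarray:
        """Expected particles/mm^2 in each size bin under the mixture model.

        Bins are half-open, ``[0, e1), [e1, e2), ..., [ek, inf)``.
        """
        bounds = np.concatenate([[0.0], np.asarray(edges, dtype=float), [np.inf]])
        lam = np.zeros(len(bounds) - 1)
        for m in self.morphologies.values():
            dist = m.size_distribution()
            cdf = np.array([dist.cdf(b) if np.isfinite(b) else 1.0 for b in bounds])
            lam += m.density_per_mm2 * np.diff(cdf)
        return lam


def _cond(name, dot, crystal, cotton, bubbles=0.3, edge=True) -> ConditionSpec:
    return ConditionSpec(
        name=name,
        morphologies={
            "black_dot": MorphologySpec(*dot),
            "crystal": MorphologySpec(*crystal),
            "cotton": MorphologySpec(*cotton),
        },
        bubble_density_per_mm2=bubbles,
        edge_artifact=edge,
    )


#: Default condition table.  Densities are particles/mm^2; size models are
#: (density, median um, geometric SD) per morphology.  The small-fragment
#: density of condition A is set near the reported small-particle density
#: scale for the no-coating-removal protocol.
DEFAULT_CONDITIONS: Dict[str, ConditionSpec] = {
    "A": _cond("A", dot=(245.0, 28.0, 1.6), crystal=(3.0, 160.0, 1.5), cotton=(4.0, 140.0, 1.5)),
    "B": _cond("B", dot=(40.0, 35.0, 1.7), crystal=(5.0, 260.0, 1.6), cotton=(1.5, 330.0, 1.7)),
    "C": _cond("C", dot=(60.0, 32.0, 1.6), crystal=(8.0, 210.0, 1.45), cotton=(7.0, 190.0, 1.45)),
    "D": _cond("D", dot=(15.0, 25.0, 1.5), crystal=(1.2, 150.0, 1.4), cotton=(0.8, 140.0, 1.4)),
    "blank": _cond(
        "blank",
        dot=(0.01, 20.0, 1.4),
        crystal=(0.0, 150.0, 1.4),
        cotton=(0.0, 140.0, 1.4),
        bubbles=0.2,
        edge=False,
    ),
}


@dataclass(frozen=True)
class MethodRecoveryParams:
    """Replicate model for morphine mass measurements of one protocol.

    ``extracted`` refers to morphine in the cotton-filtered solution,
    ``remaining`` to morphine washed back out of the cotton ball.  Units mg.
    """

    n: int
    extracted_mean_mg: float
    extracted_sd_mg: float
    remaining_mean_mg: float
    remaining_sd_mg: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")
        for v in (self.extracted_sd_mg, self.remaining_sd_mg):
            if v < 0:
                raise ValueError("standard deviations must be >= 0")


#: Reported replicate summary statistics for the four protocols: six
#: tablets for A and C, three each for B and D.
DEFAULT_RECOVERY_PARAMS: Dict[str, MethodRecoveryParams] = {
    "A": MethodRecoveryParams(6, 32.5, 13.2, 7.7, 1.8),
    "B": MethodRecoveryParams(3, 31.8, 2.4, 9.2, 1.8),
    "C": MethodRecoveryParams(6, 32.4, 12.9, 7.6, 1.1),
    "D": MethodRecoveryParams(3, 31.3, 2.3, 5.2, 0.8),
}
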