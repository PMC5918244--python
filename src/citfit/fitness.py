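"""Relative fitness from serial-transfer competition assays.

Two strains are mixed, plated to count initial densities, propagated
through daily 1:100 transfers, and plated again.  Each competitor's
Malthusian parameter (realized exponential growth rate) is computed
between the two platings, correcting for the dilution factor applied at
the transfers between them, and relative fitness W is the ratio of the
two Malthusian parameters.  W = 1 is selective neutrality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: counts outside this range are unreliable on a standard plate; they are
#: warned about, never corrected.
COUNTABLE_RANGE = (30, 300)


@dataclass(frozen=True)
class PlateCount:
    """One plating observation: colonies counted after diluting a sample.

    ``colonies`` is a non-negative count.  It is allowed to be fractional
    so that noise-free simulated assays can carry exact expected counts;
    observed plate data is always integral.
    """

    colonies: float
    plating_dilution: float = 1.0
    volume_plated: float = 1.0  # ml

    def __post_init__(self) -> None:
        if self.colonies < 0 or not math.isfinite(self.colonies):
            raise ValueError(f"colonies must be finite and >= 0, got {self.colonies}")
        if self.plating_dilution < 1:
            raise ValueError(f"plating_dilution must be >= 1, got {self.plating_dilution}")
        if self.volume_plated <= 0:
            raise ValueError(f"volume_plated must be > 0, got {self.volume_plated}")


@dataclass(frozen=True)
class CompetitionAssay:
    """One replicate competition flask.

    ``competitor_a`` is the focal strain (typically Ara^-), ``competitor_b``
    the reference (typically Ara^+).  ``days`` growth cycles separate the
    initial and final platings, with ``transfer_dilution``-fold dilutions at
    the ``days - 1`` intervening transfers.
    """

    assay_id: str
    competitor_a: str
    competitor_b: str
    initial_a: PlateCount
    initial_b: PlateCount
    final_a: PlateCount
    final_b: PlateCount
    days: int = 3
    transfer_dilution: float = 100.0
    competition_class: str = "cit_effect"
    replicate_id: str = ""

    VALID_CLASSES = ("ara_marker", "cit_effect", "population_context")

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError(f"days must be >= 1, got {self.days}")
        if self.transfer_dilution <= 1:
            raise ValueError(f"transfer_dilution must be > 1, got {self.transfer_dilution}")
        if self.competition_class not in self.VALID_CLASSES:
            raise ValueError(
                f"competition_class must be one of {self.VALID_CLASSES}, "
                f"got {self.competition_class!r}"
            )


@dataclass(frozen=True)
class FitnessEstimate:
    """Relative fitness W = m_a / m_b with the per-day growth rates."""

    w: float
    m_a: float
    m_b: float
    assay_id: str = ""


def density_from_count(p: PlateCount) -> float:
    """CFU/ml implied by a plating: colonies x dilution / volume.

    A zero-colony plate returns density 0 with a logged warning; the
    density is unresolvable and downstream operations must reject it.
    """
    if p.colonies == 0:
        logger.warning(
            "zero colonies on plate (dilution %g, volume %g ml): density unresolvable",
            p.plating_dilution, p.volume_plated,
        )
        return 0.0
    if p.colonies == int(p.colonies) and not (
        COUNTABLE_RANGE[0] <= p.colonies <= COUNTABLE_RANGE[1]
    ):
        logger.warning(
            "colony count %g outside countable range %s; using as-is",
            p.colonies, COUNTABLE_RANGE,
        )
    return p.colonies * p.plating_dilution / p.volume_plated


def realized_growth(
    d_initial: float, d_final: float, days: int = 3, transfer_dilution: float = 100.0
) -> float:
    """Malthusian parameter m (per day) between two platings.

    The platings bracket ``days`` growth cycles with ``days - 1``
    intervening ``transfer_dilution``-fold transfers, so the net expansion
    to attribute to growth is ``d_final * F**(days-1) / d_initial``::

        m = ln(d_final * F**(days-1) / d_initial) / days
    """
    if d_initial <= 0:
        raise ValueError(f"initial density must be > 0, got {d_initial}")
    if d_final <= 0:
        raise ValueError(f"final density must be > 0, got {d_final}")
    expansion = d_final * transfer_dilution ** (days - 1) / d_initial
    return math.log(expansion) / days


def relative_fitness(assay: CompetitionAssay) -> FitnessEstimate:
    """Relative fitness of competitor A versus competitor B.

    W = m_a / m_b, each m computed by :func:`realized_growth` with the
    assay's days and transfer dilution.  The per-day normalization cancels
    in the ratio.  Raises if any plating gives a non-positive density or
    the reference failed to grow (m_b <= 0).
    """
    dens = {}
    for name in ("initial_a", "initial_b", "final_a", "final_b"):
        d = density_from_count(getattr(assay, name))
        if d <= 0:
            raise ValueError(
                f"assay {assay.assay_id!r}: plating {name} has non-positive "
                f"density {d}; replicate invalid"
            )
        dens[name] = d
    m_a = realized_growth(dens["initial_a"], dens["final_a"], assay.days, assay.transfer_dilution)
    m_b = realized_growth(dens["initial_b"], dens["final_b"], assay.days, assay.transfer_dilution)
    if m_b <= 0:
        raise ValueError(
            f"assay {assay.assay_id!r}: reference strain {assay.competitor_b!r} "
            f"failed to grow (m_b = {m_b:.4g}); assay invalid"
        )
    return FitnessEstimate(w=m_a / m_b, m_a=m_a, m_b=m_b, assay_id=assay.assay_id)


def pool_replicates(ws) -> tuple[float, float, int, tuple[float, float]]:
    """Mean, SD, n and symmetric t-based 95% CI of replicate W values."""
    ws = np.asarray(ws, dtype=float)
    n = ws.size
    if n < 2:
        raise ValueError(f"need >= 2 replicates, got {n}")
    mean = float(ws.mean())
    sd = float(ws.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return mean, sd, n, (mean - half, mean + half)
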