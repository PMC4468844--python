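"""Poisson model of droplet/bead loading.

In emulsion barcoding, barcode oligonucleotides (and later genomic
fragments) are distributed over compartments at a mean rate of lambda
copies per bead (c.p.b.).  The number of molecules landing in one
compartment is then Poisson(lambda), which yields closed forms for the
fraction of beads that receive at least one molecule (the expected
enrichment yield) and for the fraction of occupied compartments that are
monoclonal, i.e. received exactly one molecule.  These expectations are
used both to predict experimental outcomes and as an oracle for the
simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = [
    "LoadingModel",
    "occupancy_probability",
    "monoclonal_fraction",
    "expected_oligo_count",
    "expected_enriched_beads",
]


@dataclass(frozen=True)
class LoadingModel:
    """Poisson loading of molecules onto beads.

    Parameters
    ----------
    cpb
        Mean copies per bead (the Poisson rate lambda); dimensionless, >= 0.
    n_beads
        Number of beads in the reaction; >= 0.
    """

    cpb: float
    n_beads: int = 0

    def __post_init__(self) -> None:
        if self.cpb < 0:
            raise InvalidParameterError(f"cpb must be >= 0, got {self.cpb}")
        if self.n_beads < 0:
            raise InvalidParameterError(
                f"n_beads must be >= 0, got {self.n_beads}"
            )


def occupancy_probability(model: LoadingModel) -> float:
    """P(K >= 1) for K ~ Poisson(cpb): the expected enriched-bead fraction.

    At cpb = 0.1 this is 1 - exp(-0.1) ~= 0.0952, i.e. roughly 10% of beads
    are expected to carry at least one barcode molecule.
    """
    return -math.expm1(-model.cpb)


def monoclonal_fraction(model: LoadingModel) -> float:
    """P(K = 1 | K >= 1) for K ~ Poisson(cpb).

    The expected fraction of *occupied* compartments that received exactly
    one molecule.  Tends to 1 as cpb -> 0+ and decreases monotonically:
    rare loading is almost always single.
    """
    if model.cpb <= 0:
        raise InvalidParameterError(
            f"monoclonal_fraction requires cpb > 0, got {model.cpb}"
        )
    # lambda e^-l / (1 - e^-l) == lambda / (e^l - 1); expm1 keeps small-lambda
    # evaluation accurate.
    return model.cpb / math.expm1(model.cpb)


def expected_oligo_count(model: LoadingModel) -> float:
    """Expected number of barcode molecules in the reaction: n_beads * cpb."""
    return model.n_beads * model.cpb


def expected_enriched_beads(model: LoadingModel) -> float:
    """Expected number of beads carrying >= 1 molecule: n_beads * P(K >= 1)."""
    return model.n_beads * occupancy_probability(model)


def summary_table(model: LoadingModel) -> dict[str, float]:
    """All four loading expectations as a flat dict (used by the CLI)."""
    out = {
        "cpb": model.cpb,
        "n_beads": float(model.n_beads),
        "occupancy_probability": occupancy_probability(model),
        "expected_oligo_count": expected_oligo_count(model),
        "expected_enriched_beads": expected_enriched_beads(model),
    }
    if model.cpb > 0:
        out["monoclonal_fraction"] = monoclonal_fraction(model)
    return out
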