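"""Mechanistic model of the dual-luciferase A-to-I editing reporter.

The reporter transcript carries firefly luciferase (FFL) upstream of a
GluA2-derived hairpin in which the R/G site has been recoded to an amber
stop codon. Every transcript makes FFL; only transcripts edited at the stop
codon read through into an in-frame Nanoluciferase (Nluc) fusion. The
Nluc/FFL luminescence ratio is therefore an editing statistic that cancels
well-to-well differences in cell number and transcription.

The model here maps an editing fraction ``e`` and a compound's latent
action to expected channel signals:

    FFL  = A * [(1 - e) + s * e]
    Nluc = A * e * s * beta * eta

where ``A`` is a transcript/translation amplitude, ``s`` in (0, 1] the
steady-state level of the FFL-Nluc fusion relative to free FFL (the fusion
is destabilised in cells), ``beta`` the per-molecule Nluc:FFL brightness
ratio, and ``eta`` an Nluc-enzyme inhibition factor. Compound action enters
through a Hill occupancy f = max_effect * dose^h / (dose^h + IC50^h).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass


class Action(str, enum.Enum):
    """Latent mechanism class of a screened compound."""

    INACTIVE = "inactive"
    EDITING_INHIBITOR = "editing_inhibitor"
    EDITING_ACTIVATOR = "editing_activator"
    NLUC_ENZYME_INHIBITOR = "nluc_enzyme_inhibitor"
    CYTOTOXIC = "cytotoxic"


@dataclass(frozen=True)
class ReporterParams:
    """Reporter-line parameters.

    beta
        Per-molecule Nluc-to-FFL brightness ratio; Nluc luminescence is
        more than two orders of magnitude brighter than FFL (default 150).
    s
        Fusion-protein stability factor in (0, 1]: steady-state FFL-Nluc
        fusion level relative to free FFL. The measured ratio sits far
        below the naive ``beta * e`` prediction because the fusion is
        rapidly turned over; the default 0.01 reproduces that behaviour
        qualitatively and is a free simulator parameter, not an estimate.
    e0
        Baseline editing fraction of the cell line (default 0.39, the
        editing level of the high-editing HeLa reporter clone).
    amplitude
        Transcript/translation scale in arbitrary luminescence counts.
    """

    beta: float = 150.0
    s: float = 0.01
    e0: float = 0.39
    amplitude: float = 1e6

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not 0 < self.s <= 1:
            raise ValueError("s must be in (0, 1]")
        if not 0 <= self.e0 <= 1:
            raise ValueError("e0 must be in [0, 1]")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class CompoundEffect:
    """A compound's latent action and potency."""

    action: Action = Action.INACTIVE
    ic50: float | None = None  # uM
    hill: float = 1.0
    max_effect: float = 1.0  # fraction of complete action at saturation

    def __post_init__(self) -> None:
        object.__setattr__(self, "action", Action(self.action))
        if self.action is not Action.INACTIVE:
            if self.ic50 is None or not self.ic50 > 0:
                raise ValueError(f"{self.action.value} requires ic50 > 0")
        if not 0 <= self.max_effect <= 1:
            raise ValueError("max_effect must be in [0, 1]")
        if not self.hill > 0:
            raise ValueError("hill must be > 0")


def hill_occupancy(dose: float, ic50: float, hill: float = 1.0, max_effect: float = 1.0) -> float:
    """Fractional occupancy ``max_effect * dose^h / (dose^h + ic50^h)``."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return 0.0
    d, i = dose**hill, ic50**hill
    return max_effect * d / (d + i)


def expected_signals(
    params: ReporterParams, effect: CompoundEffect, dose: float
) -> tuple[float, float]:
    """Expected (FFL, Nluc) for one well before measurement noise.

    Editing inhibitors scale the edited fraction down by the occupancy,
    activators pull it toward 1 symmetrically, Nluc-enzyme inhibitors
    quench the Nluc channel only, and cytotoxic compounds attenuate both
    channels (leaving the ratio invariant — the basis of the FFL toxicity
    filter). ``dose = 0`` or an inactive compound returns the unperturbed
    pair.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    f = 0.0
    if effect.action is not Action.INACTIVE and dose > 0:
        f = hill_occupancy(dose, effect.ic50, effect.hill, effect.max_effect)

    e = params.e0
    if effect.action is Action.EDITING_INHIBITOR:
        e = params.e0 * (1.0 - f)
    elif effect.action is Action.EDITING_ACTIVATOR:
        e = params.e0 + (1.0 - params.e0) * f

    ffl = params.amplitude * ((1.0 - e) + params.s * e)
    eta = (1.0 - f) if effect.action is Action.NLUC_ENZYME_INHIBITOR else 1.0
    nluc = params.amplitude * e * params.s * params.beta * eta

    if effect.action is Action.CYTOTOXIC:
        ffl *= 1.0 - f
        nluc *= 1.0 - f
    return ffl, nluc


def naive_ratio(e: float, beta: float) -> float:
    """Expected Nluc/FFL ratio under the naive brightness-only model.

    Ignores fusion instability and FFL depletion: a 1% edited pool with a
    150-fold brighter Nluc would read out at ratio 1.5, and full editing
    at 150. The measured ratio sits well below this, which is what the
    stability factor ``s`` in :func:`expected_signals` absorbs.
    """
    if not 0 <= e <= 1:
        raise ValueError("editing fraction must be in [0, 1]")
    return beta * e


def editing_dose_curve(dose: float, e_max: float, k: float) -> float:
    """Saturating editing fraction ``e_max * (1 - exp(-k * dose))``.

    ``dose`` is an ADAR-expression surrogate (e.g. transfected plasmid
    amount). The form makes editing rise log-like in dose while the
    reporter ratio stays near-linear in dose, so the ratio is convex
    (exponential-looking) when plotted against editing percent.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if not 0 < e_max <= 1:
        raise ValueError("e_max must be in (0, 1]")
    if not k > 0:
        raise ValueError("k must be > 0")
    return e_max * (1.0 - math.exp(-k * dose))
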