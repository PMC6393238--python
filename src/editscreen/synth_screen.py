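"""Synthetic dual-luciferase screen generator.

Produces complete 384-well screens — plates in the standard layout
(compounds in columns 1-22, 0.1% DMSO vehicle in column 23, 10 uM
Nluc-enzyme inhibitor in column 24), per-compound latent ground truth, and
multiplicative lognormal well noise — plus synthetic Sanger peak-height
traces, so every analysis stage is testable without external data.

Noise is multiplicative lognormal rather than additive Gaussian:
luminescence counts are positive and their spread is CV-stable, and a
lognormal can never produce a negative count. The positive-control wells
use a Nluc-enzyme inhibitor with IC50 0.08 uM, the potency of the
best-characterised control inhibitor, so at the 10 uM screening dose the
Nluc channel is quenched by ~99.2% while FFL is untouched.

Ground-truth labels make the designed false-positive class explicit:
Nluc-enzyme inhibitors pass the ratio threshold exactly like editing
inhibitors and are separable only by a counter-screen, not by this assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_model import (
    COMPOUND_COLUMNS,
    ROW_LETTERS,
    Plate,
    Role,
    Well,
    WellAddress,
    all_addresses,
    default_layout,
)
from .reporter_model import Action, CompoundEffect, ReporterParams, expected_signals

COMPOUND_WELLS_PER_PLATE = len(COMPOUND_COLUMNS) * len(ROW_LETTERS)  # 352

#: Positive control: Nluc-enzyme inhibitor 1, IC50 0.08 uM, dosed at 10 uM.
POS_CONTROL_EFFECT = CompoundEffect(
    action=Action.NLUC_ENZYME_INHIBITOR, ic50=0.08, hill=1.0, max_effect=1.0
)
NEG_CONTROL_EFFECT = CompoundEffect(action=Action.INACTIVE)

GROUND_TRUTH_COLUMNS = [
    "compound_id",
    "action",
    "ic50",
    "hill",
    "max_effect",
    "plate_id",
    "well",
    "expected_ffl",
    "expected_nluc",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise model for one screen.

    ``cv_ffl``/``cv_nluc`` are coefficients of variation of the
    multiplicative lognormal well noise per channel (defaults 0.08, which
    puts a default plate's Z' in the mid-0.6s, the quality band of a good
    campaign). ``read_decay_*`` are the fractional signal losses per hour
    between reagent addition and the read: FFL luminescence decays with a
    one-hour half-life (0.5/h) while the glow-type Nluc signal is stable.
    """

    cv_ffl: float = 0.08
    cv_nluc: float = 0.08
    read_decay_ffl: float = 0.5
    read_decay_nluc: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_ffl < 0 or self.cv_nluc < 0:
            raise ValueError("CVs must be >= 0")
        for name in ("read_decay_ffl", "read_decay_nluc"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass(frozen=True)
class LibrarySpec:
    """Composition of the synthetic compound library.

    ``frac_by_action`` gives the proportion of each latent mechanism class;
    the defaults are illustrative (the true mechanism mix behind a primary
    hit list is unknown without counter-screens) and sized so a default
    screen yields a sub-percent primary hit rate. Potencies are drawn
    log-uniformly per action from ``potency_range_uM``.
    """

    n_compounds: int = 33000
    frac_by_action: Mapping[Action, float] = field(
        default_factory=lambda: {
            Action.INACTIVE: 0.9765,
            Action.EDITING_INHIBITOR: 0.006,
            Action.EDITING_ACTIVATOR: 0.0025,
            Action.NLUC_ENZYME_INHIBITOR: 0.005,
            Action.CYTOTOXIC: 0.01,
        }
    )
    potency_range_uM: tuple[float, float] | Mapping[Action, tuple[float, float]] = (
        0.01,
        10.0,
    )

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        fracs = {Action(a): float(v) for a, v in self.frac_by_action.items()}
        if any(v < 0 for v in fracs.values()):
            raise ValueError("action fractions must be non-negative")
        if not math.isclose(sum(fracs.values()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"action fractions sum to {sum(fracs.values())}, not 1")
        object.__setattr__(self, "frac_by_action", fracs)
        for lo, hi in self._potency_ranges().values():
            if not 0 < lo <= hi:
                raise ValueError("potency ranges must satisfy 0 < lo <= hi")

    def _potency_ranges(self) -> dict[Action, tuple[float, float]]:
        """Per-action IC50 range; a bare tuple applies to every action."""
        if isinstance(self.potency_range_uM, Mapping):
            ranges = {Action(a): tuple(v) for a, v in self.potency_range_uM.items()}
            default = (0.01, 10.0)
            return {a: ranges.get(a, default) for a in Action}
        return {a: tuple(self.potency_range_uM) for a in Action}

    @property
    def plates_per_screen(self) -> int:
        return math.ceil(self.n_compounds / COMPOUND_WELLS_PER_PLATE)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def draw_library(lib: LibrarySpec, rng: np.random.Generator) -> list[CompoundEffect]:
    """Assign each compound an action class and potency by seeded draw."""
    actions = list(lib.frac_by_action)
    probs = np.array([lib.frac_by_action[a] for a in actions], dtype=float)
    probs /= probs.sum()
    picks = rng.choice(len(actions), size=lib.n_compounds, p=probs)
    ranges = lib._potency_ranges()
    unit = rng.uniform(0.0, 1.0, size=lib.n_compounds)
    effects = []
    for k, u in zip(picks, unit):
        action = actions[int(k)]
        if action is Action.INACTIVE:
            effects.append(CompoundEffect(action=Action.INACTIVE))
        else:
            lo, hi = ranges[action]
            ic50 = math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))
            effects.append(
                CompoundEffect(action=action, ic50=ic50, hill=1.0, max_effect=1.0)
            )
    return effects


def _control_effect(role: Role) -> CompoundEffect:
    return POS_CONTROL_EFFECT if role is Role.POS_CONTROL else NEG_CONTROL_EFFECT


def _build_plates(
    effects: Mapping[str, CompoundEffect],
    params: ReporterParams,
    noise: NoiseConfig,
    dose: float,
    rng: np.random.Generator,
    plate_prefix: str,
    read_delay_h: float = 0.0,
    gradient: float = 0.0,
) -> tuple[list[Plate], pd.DataFrame]:
    """Lay compounds into standard-layout plates and apply noise.

    ``gradient`` adds an optional linear row/column systematic (fractional
    amplitude across the plate diagonal) for robustness testing; it is off
    by default because well-behaved campaigns show no plate effects.
    """
    layout = default_layout()
    decay_ffl = (1.0 - noise.read_decay_ffl) ** read_delay_h
    decay_nluc = (1.0 - noise.read_decay_nluc) ** read_delay_h

    compound_ids = list(effects)
    plates: list[Plate] = []
    truth_rows: list[dict] = []
    n_plates = max(1, math.ceil(len(compound_ids) / COMPOUND_WELLS_PER_PLATE))
    idx = 0
    for p in range(n_plates):
        plate_id = f"{plate_prefix}{p + 1:03d}"
        addresses = sorted(all_addresses())
        exp_ffl = np.empty(len(addresses))
        exp_nluc = np.empty(len(addresses))
        meta: list[tuple[WellAddress, Role, str | None, float]] = []
        for i, addr in enumerate(addresses):
            role = layout[addr]
            cid: str | None = None
            well_dose = 0.0
            if role is Role.COMPOUND:
                if idx < len(compound_ids):
                    cid = compound_ids[idx]
                    idx += 1
                    effect = effects[cid]
                    well_dose = dose
                else:
                    role = Role.EMPTY
                    effect = NEG_CONTROL_EFFECT
            else:
                effect = _control_effect(role)
                well_dose = dose if role is Role.POS_CONTROL else 0.0
            ffl, nluc = expected_signals(params, effect, well_dose)
            if gradient:
                g = 1.0 + gradient * (
                    (ROW_LETTERS.index(addr.row) / 15.0 + (addr.column - 1) / 23.0) / 2.0
                    - 0.5
                )
                ffl, nluc = ffl * g, nluc * g
            exp_ffl[i], exp_nluc[i] = ffl * decay_ffl, nluc * decay_nluc
            meta.append((addr, role, cid, well_dose))
            if cid is not None:
                truth_rows.append(
                    {
                        "compound_id": cid,
                        "action": effects[cid].action.value,
                        "ic50": effects[cid].ic50,
                        "hill": effects[cid].hill,
                        "max_effect": effects[cid].max_effect,
                        "plate_id": plate_id,
                        "well": str(addr),
                        "expected_ffl": exp_ffl[i],
                        "expected_nluc": exp_nluc[i],
                    }
                )
        obs_ffl = exp_ffl * _lognormal_factor(rng, noise.cv_ffl, len(addresses))
        obs_nluc = exp_nluc * _lognormal_factor(rng, noise.cv_nluc, len(addresses))
        wells = {
            addr: Well(
                addr,
                role,
                cid,
                well_dose,
                None if role is Role.EMPTY else float(obs_ffl[i]),
                None if role is Role.EMPTY else float(obs_nluc[i]),
            )
            for i, (addr, role, cid, well_dose) in enumerate(meta)
        }
        plates.append(Plate(plate_id, wells))
    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    return plates, truth


def simulate_screen(
    params: ReporterParams | None = None,
    lib: LibrarySpec | None = None,
    noise: NoiseConfig | None = None,
    dose: float = 10.0,
    read_delay_h: float = 0.0,
    gradient: float = 0.0,
) -> tuple[list[Plate], pd.DataFrame]:
    """Simulate a full single-concentration screen.

    Returns the plates and a ground-truth table (one row per compound
    well: latent action, IC50 and pre-noise expected signals). The draw is
    deterministic given ``noise.seed``.
    """
    params = params or ReporterParams()
    lib = lib or LibrarySpec()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(noise.seed)
    effects = draw_library(lib, rng)
    named = {f"CMPD-{i + 1:06d}": eff for i, eff in enumerate(effects)}
    return _build_plates(
        named, params, noise, dose, rng, plate_prefix="SYN-", read_delay_h=read_delay_h,
        gradient=gradient,
    )


def simulate_dose_plates(
    effects: Mapping[str, CompoundEffect],
    params: ReporterParams | None = None,
    noise: NoiseConfig | None = None,
    doses: Sequence[float] = (2.5, 5.0, 10.0),
    seed: int | None = None,
) -> dict[float, list[Plate]]:
    """Independent confirmation experiment: re-plate compounds at each dose.

    Each dose gets its own plates (standard layout with fresh controls) and
    fresh noise, emulating the independent retest of primary hits.
    """
    params = params or ReporterParams()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    tables: dict[float, list[Plate]] = {}
    for dose in doses:
        plates, _ = _build_plates(
            effects, params, noise, dose, rng, plate_prefix=f"RT{dose:g}-"
        )
        tables[dose] = plates
    return tables


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth[["compound_id", "action", "ic50"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic Sanger traces

TRACE_COLUMNS = ["position", "base", "A", "C", "G", "T"]


def simulate_trace(
    edit_pct: float,
    site_index: int,
    context: str,
    peak_noise_cv: float = 0.0,
    seed: int | None = None,
    secondary_edits: Mapping[int, float] | None = None,
    baseline: float = 0.0,
    full_height: float = 1000.0,
) -> pd.DataFrame:
    """Synthetic per-position chromatogram peak heights for A, C, G, T.

    At ``site_index`` (which must call an A in ``context``) the G peak is
    proportional to ``edit_pct`` and the A peak to ``100 - edit_pct`` —
    the mixed A/G peak of a partially edited template. ``secondary_edits``
    plants additional edited adenosines (position -> percent) to emulate
    off-target editing. All peaks receive independent multiplicative
    lognormal noise of CV ``peak_noise_cv``. ``baseline`` (fraction of
    ``full_height``) adds a flat floor under every channel; the default 0
    keeps G/(A+G) recovery exact at zero noise.
    """
    if not 0 <= edit_pct <= 100:
        raise ValueError("edit_pct must be in [0, 100]")
    if not 0 <= site_index < len(context):
        raise ValueError(f"site_index {site_index} outside sequence of length {len(context)}")
    if context[site_index].upper() != "A":
        raise ValueError(f"context position {site_index} is {context[site_index]!r}, not A")
    edits = {site_index: edit_pct}
    for pos, pct in (secondary_edits or {}).items():
        if not 0 <= pos < len(context):
            raise ValueError(f"secondary edit position {pos} outside sequence")
        if context[pos].upper() != "A":
            raise ValueError(f"secondary edit position {pos} is not an A")
        edits[pos] = float(pct)

    rng = np.random.default_rng(seed)
    floor = baseline * full_height
    rows = []
    for pos, base in enumerate(context.upper()):
        heights = {b: floor for b in "ACGT"}
        if pos in edits:
            pct = edits[pos]
            heights["G"] += full_height * pct / 100.0
            heights["A"] += full_height * (100.0 - pct) / 100.0
        else:
            heights[base] += full_height
        if peak_noise_cv > 0:
            for b in "ACGT":
                heights[b] *= float(_lognormal_factor(rng, peak_noise_cv, 1)[0])
        rows.append({"position": pos, "base": base, **heights})
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)
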