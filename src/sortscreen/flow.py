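"""Two-channel reporter cytometry: simulation and ratio gating.

The readout emulated here is a tandem autophagic-flux reporter: a cleaved
probe yields equimolar GFP-LC3 and free RFP, lysosomal delivery quenches
the GFP moiety while RFP stays cytosolic, so autophagic flux lowers the
GFP:RFP ratio. "Activated" cells are those whose log10(GFP/RFP) falls
below a gate set from a control (unactivated) sample's lower quantile;
the activated fraction of a sample is the screen's quantitative readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_GATE_QUANTILE = 0.01

# Location/scale of the RFP (internal control) channel in log10 a.u.;
# they cancel in the ratio and only set the absolute scale of events.
_RFP_LOG10_MEAN = 4.0
_RFP_LOG10_SD = 0.4


@dataclass
class GateResult:
    """Outcome of gating one sample at a fixed log-ratio threshold."""

    threshold: float
    n_total: int
    n_gated: int

    @property
    def fraction(self) -> float:
        return self.n_gated / self.n_total


def simulate_events(
    n: int,
    activated_fraction: float,
    flux_log_drop: float = 1.0,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate n events of a two-channel ratio reporter.

    RFP is log-normal; baseline GFP equals RFP times log-normal ratio noise
    (sd ``noise_sd`` in log10), so log10(GFP/RFP) is centered at 0 for
    unactivated cells. An ``activated_fraction`` of events additionally
    have log10(GFP) reduced by ``flux_log_drop`` (quenching of the GFP
    moiety by lysosomal delivery). Returns a frame with columns
    ``gfp``, ``rfp``, ``activated`` (the latter is simulation truth, not
    part of the measured channels).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= activated_fraction <= 1.0:
        raise ValueError("activated_fraction must be in [0, 1]")
    if flux_log_drop < 0:
        raise ValueError("flux_log_drop must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    log_rfp = rng.normal(_RFP_LOG10_MEAN, _RFP_LOG10_SD, size=n)
    log_ratio = rng.normal(0.0, noise_sd, size=n)
    activated = rng.random(n) < activated_fraction
    log_gfp = log_rfp + log_ratio - np.where(activated, flux_log_drop, 0.0)
    return pd.DataFrame(
        {"gfp": 10.0 ** log_gfp, "rfp": 10.0 ** log_rfp, "activated": activated}
    )


def _log_ratio(events: pd.DataFrame) -> np.ndarray:
    gfp = events["gfp"].to_numpy(dtype=float)
    rfp = events["rfp"].to_numpy(dtype=float)
    if (gfp <= 0).any() or (rfp <= 0).any():
        raise ValueError("fluorescence intensities must be strictly positive")
    return np.log10(gfp / rfp)


def set_gate(control: pd.DataFrame, quantile: float = DEFAULT_GATE_QUANTILE) -> float:
    """Gate threshold: the given lower quantile of the control sample's
    log10(GFP/RFP). quantile = 0 places the gate below every control event."""
    if len(control) == 0:
        raise ValueError("control sample is empty")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    ratios = _log_ratio(control)
    if quantile == 0.0:
        return float(ratios.min()) - 1e-9  # strictly below all control events
    return float(np.quantile(ratios, quantile))


def activated_fraction(sample: pd.DataFrame, threshold: float) -> GateResult:
    """Count events strictly below the threshold in log-ratio space."""
    if len(sample) == 0:
        raise ValueError("sample is empty")
    ratios = _log_ratio(sample)
    n_gated = int((ratios < threshold).sum())  # ties at threshold not gated
    return GateResult(threshold=float(threshold), n_total=len(sample), n_gated=n_gated)


def estimate_activated_fraction(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    quantile: float = DEFAULT_GATE_QUANTILE,
) -> float:
    """Background-corrected activated fraction.

    With the gate at the control's q-quantile, a fraction q of unactivated
    events falls in the gate by construction; assuming activated events are
    (nearly) all gated, observed = a + (1 - a)·q, inverted here as
    a = (observed - q) / (1 - q), clipped to [0, 1].
    """
    threshold = set_gate(control, quantile)
    observed = activated_fraction(sample, threshold).fraction
    if quantile >= 1.0:
        raise ValueError("quantile must be < 1 for background correction")
    return float(np.clip((observed - quantile) / (1.0 - quantile), 0.0, 1.0))


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a two-column CSV (``gfp,rfp``) event table."""
    events = pd.read_csv(path)
    missing = {"gfp", "rfp"} - set(events.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events[[c for c in ("gfp", "rfp") if c in events.columns]].to_csv(path, index=False)


def read_events_fcs(path: str | Path, gfp_channel: str, rfp_channel: str) -> pd.DataFrame:
    """Optional FCS ingestion (requires the ``fcsparser`` package)."""
    try:
        import fcsparser  # type: ignore
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "FCS ingestion requires the optional 'fcsparser' package; "
            "use the native two-column CSV format instead"
        ) from err
    _, data = fcsparser.parse(str(path))  # pragma: no cover
    return pd.DataFrame({"gfp": data[gfp_channel], "rfp": data[rfp_channel]})  # pragma: no cover
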