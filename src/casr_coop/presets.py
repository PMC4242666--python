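"""Construct presets: WT CaSR and the four hinge-region "toggle" mutants.

Each preset bundles the published functional parameters of one construct —
EC50 and Hill coefficient of the [Ca2+]i population response, IP1
accumulation and ERK1/2 phosphorylation (each with and without 5 mM L-Phe),
the L-Phe concentration-response EC50, and the single-cell oscillation
phenotype (onset/plateau threshold distributions and peaks-per-minute
rates) — so the generators can produce data with those values as ground
truth and the pipeline can be validated by recovering them.

The loss-of-function variants (L173P, P221Q) raise EC50s and thresholds;
L173P's [Ca2+]i dose-response is biphasic. The gain-of-function variants
(L173F, P221L) lower them. L-Phe left-shifts the responsive constructs.

Hill coefficients for the IP1, ERK and L-Phe readouts were not reported;
the presets use n = 3 (IP1/ERK, matching the strongly cooperative Ca2+
response) and n = 2 (L-Phe) as plausible defaults. Threshold medians and
cell-to-cell CVs are calibrated so that the modal starting/ending steps and
their modal fractions match the reported single-cell distributions (e.g.
~53% of oscillatory WT cells starting at the 3.0 mM step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .cooperativity import HillParams
from .protocol import StepProtocol
from .synthdata import PopulationParams, RateFn, constant_rate

__all__ = ["OscillationPreset", "ConstructPreset", "PRESETS", "get_preset"]

IP1_MAX_INHIBITION_PCT = 75.0  # plateau of the percent-inhibition readout
IP1_HILL_N = 3.0
ERK_HILL_N = 3.0
PHE_HILL_N = 2.0


@dataclass(frozen=True)
class OscillationPreset:
    """Single-cell oscillation phenotype under one L-Phe condition."""

    onset_median_mM: float
    onset_cv: float
    plateau_median_mM: float
    plateau_cv: float
    freq_ppm: float


@dataclass(frozen=True)
class ConstructPreset:
    """All published functional parameters for one CaSR construct."""

    name: str
    # [Ca2+]i population dose-response (normalized 0..1)
    cai: Optional[HillParams]
    cai_phe: Optional[HillParams]
    # biphasic [Ca2+]i response: (phase1, phase2, fraction of amplitude in phase 1)
    cai_biphasic: Optional[tuple[HillParams, HillParams, float]] = None
    cai_biphasic_phe: Optional[tuple[HillParams, HillParams, float]] = None
    # IP1 percent-inhibition EC50s (curve 0..IP1_MAX_INHIBITION_PCT)
    ip1_ec50: Optional[float] = None
    ip1_ec50_phe: Optional[float] = None
    # p-ERK normalized response EC50s
    erk_ec50: Optional[float] = None
    erk_ec50_phe: Optional[float] = None
    # L-Phe concentration-response EC50 at 1.5 mM [Ca2+]o (and at the
    # construct's own [Ca2+]o EC50, when measured)
    phe_ec50: Optional[float] = None
    phe_ec50_high_ca: Optional[float] = None
    # oscillation phenotype without / with 5 mM L-Phe
    osc: Optional[OscillationPreset] = None
    osc_phe: Optional[OscillationPreset] = None
    freq_at_mM: Optional[float] = None
    protocol_ca_mM: tuple[float, ...] = ()
    dose_conc_mM: tuple[float, ...] = ()
    ip1_conc_mM: tuple[float, ...] = ()
    erk_conc_mM: tuple[float, ...] = ()
    phe_conc_mM: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0, 12.0)

    def ip1_hill(self, with_phe: bool = False) -> HillParams:
        ec50 = self.ip1_ec50_phe if with_phe else self.ip1_ec50
        if ec50 is None:
            raise ValueError(f"{self.name}: no IP1 parameters for this condition")
        return HillParams(ec50, IP1_HILL_N, 0.0, IP1_MAX_INHIBITION_PCT)

    def erk_hill(self, with_phe: bool = False) -> HillParams:
        ec50 = self.erk_ec50_phe if with_phe else self.erk_ec50
        if ec50 is None:
            raise ValueError(f"{self.name}: no ERK parameters for this condition")
        return HillParams(ec50, ERK_HILL_N, 0.0, 1.0)

    def phe_hill(self, high_ca: bool = False) -> HillParams:
        ec50 = self.phe_ec50_high_ca if high_ca else self.phe_ec50
        if ec50 is None:
            raise ValueError(f"{self.name}: no L-Phe response for this condition")
        return HillParams(ec50, PHE_HILL_N, 0.0, 1.0)

    def rate_fn(self) -> RateFn:
        assert self.osc is not None
        phe_rate = self.osc_phe.freq_ppm if self.osc_phe else None
        return constant_rate(self.osc.freq_ppm, phe_rate)

    def population_params(
        self, n_cells: int = 50, with_phe: bool = False, fraction_nonresponding: float = 0.1
    ) -> PopulationParams:
        o = self.osc_phe if with_phe else self.osc
        if o is None:
            raise ValueError(f"{self.name}: no oscillation preset for this condition")
        return PopulationParams(
            n_cells=n_cells,
            onset_median_mM=o.onset_median_mM,
            onset_cv=o.onset_cv,
            plateau_median_mM=o.plateau_median_mM,
            plateau_cv=o.plateau_cv,
            rate_fn=self.rate_fn(),
            fraction_nonresponding=fraction_nonresponding,
        )

    def protocol(
        self, with_phe: bool = False, dwell_s: float = 180.0, sampling_dt_s: float = 1.0
    ) -> StepProtocol:
        return StepProtocol.ramp(
            self.protocol_ca_mM,
            phe_mM=5.0 if with_phe else 0.0,
            dwell_s=dwell_s,
            sampling_dt_s=sampling_dt_s,
        )


_WT_GAIN_PROTOCOL = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 8.0)
_P221Q_PROTOCOL = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.5, 10.0, 12.5, 15.0)
_L173P_PROTOCOL = (0.5, 1.0, 2.0, 3.0, 5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0, 30.0)

_WT_GAIN_DOSE = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 7.5, 10.0)
_P221Q_DOSE = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0, 15.0)
_L173P_DOSE = (0.5, 1.0, 2.0, 3.0, 5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0, 30.0)


PRESETS: dict[str, ConstructPreset] = {
    "WT": ConstructPreset(
        name="WT",
        cai=HillParams(3.0, 3.7),
        cai_phe=HillParams(1.9, 5.0),
        ip1_ec50=2.9,
        ip1_ec50_phe=2.0,
        erk_ec50=3.0,
        erk_ec50_phe=1.9,
        phe_ec50=3.7,
        osc=OscillationPreset(2.85, 0.12, 4.80, 0.15, 1.3),
        osc_phe=OscillationPreset(1.42, 0.12, 2.85, 0.12, 2.1),
        freq_at_mM=3.0,
        protocol_ca_mM=_WT_GAIN_PROTOCOL,
        dose_conc_mM=_WT_GAIN_DOSE,
        ip1_conc_mM=(0.5, 1.0, 2.0, 3.0, 5.0, 7.5, 10.0),
        erk_conc_mM=(0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0),
    ),
    "L173F": ConstructPreset(
        name="L173F",
        cai=HillParams(1.9, 3.3),
        cai_phe=HillParams(1.6, 3.7),
        ip1_ec50=1.2,
        ip1_ec50_phe=1.0,
        erk_ec50=2.7,
        erk_ec50_phe=1.6,
        phe_ec50=3.2,
        osc=OscillationPreset(1.90, 0.065, 4.30, 0.15, 1.7),
        osc_phe=OscillationPreset(1.90, 0.065, 3.80, 0.15, 1.9),
        freq_at_mM=2.5,
        protocol_ca_mM=_WT_GAIN_PROTOCOL,
        dose_conc_mM=_WT_GAIN_DOSE,
        ip1_conc_mM=(0.5, 1.0, 2.0, 3.0, 5.0, 7.5, 10.0),
        erk_conc_mM=(0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0),
    ),
    "P221L": ConstructPreset(
        name="P221L",
        cai=HillParams(2.0, 3.2),
        cai_phe=HillParams(1.7, 2.8),
        ip1_ec50=1.1,
        ip1_ec50_phe=0.9,
        erk_ec50=2.2,
        erk_ec50_phe=1.7,
        phe_ec50=4.3,
        osc=OscillationPreset(2.45, 0.18, 4.30, 0.15, 1.6),
        osc_phe=OscillationPreset(2.45, 0.18, 3.80, 0.15, 1.8),
        freq_at_mM=2.5,
        protocol_ca_mM=_WT_GAIN_PROTOCOL,
        dose_conc_mM=_WT_GAIN_DOSE,
        ip1_conc_mM=(0.5, 1.0, 2.0, 3.0, 5.0, 7.5, 10.0),
        erk_conc_mM=(0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0),
    ),
    "L173P": ConstructPreset(
        name="L173P",
        cai=None,
        cai_phe=None,
        cai_biphasic=(HillParams(3.8, 3.3), HillParams(13.0, 3.6), 0.5),
        cai_biphasic_phe=(HillParams(3.1, 2.5), HillParams(12.2, 5.8), 0.5),
        ip1_ec50=10.7,
        ip1_ec50_phe=9.0,
        erk_ec50=14.9,
        erk_ec50_phe=13.5,
        phe_ec50=5.5,
        phe_ec50_high_ca=4.9,
        osc=OscillationPreset(12.0, 0.10, 36.0, 0.20, 1.3),
        osc_phe=OscillationPreset(9.30, 0.10, 23.0, 0.12, 1.8),
        freq_at_mM=15.0,
        protocol_ca_mM=_L173P_PROTOCOL,
        dose_conc_mM=_L173P_DOSE,
        ip1_conc_mM=(3.0, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0),
        erk_conc_mM=(1.0, 3.0, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0),
    ),
    "P221Q": ConstructPreset(
        name="P221Q",
        cai=HillParams(5.2, 2.4),
        cai_phe=HillParams(3.7, 4.1),
        ip1_ec50=6.1,
        ip1_ec50_phe=4.5,
        erk_ec50=11.9,
        erk_ec50_phe=9.5,
        phe_ec50=4.5,
        phe_ec50_high_ca=2.5,
        osc=OscillationPreset(4.80, 0.15, 11.5, 0.15, 1.5),
        osc_phe=OscillationPreset(3.36, 0.12, 9.00, 0.15, 2.2),
        freq_at_mM=5.0,
        protocol_ca_mM=_P221Q_PROTOCOL,
        dose_conc_mM=_P221Q_DOSE,
        ip1_conc_mM=(1.0, 3.0, 5.0, 7.5, 10.0, 15.0),
        erk_conc_mM=(1.0, 3.0, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0),
    ),
}


def get_preset(name: str) -> ConstructPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        ) from None
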