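"""Synthetic-data generators for the whole analysis pipeline.

The generators are phenomenological surrogates for the study's three data
modalities:

* **single-cell traces** — a cell is described by two [Ca2+]o thresholds
  (oscillation onset and plateau) and a spike rate; below the onset the
  ratio sits at baseline, between the thresholds a jittered regular spike
  train rides on baseline, and at/above the plateau threshold the ratio
  holds a sustained elevation;
* **population dose-response tables** — Hill curves with multiplicative
  (CV-style) replicate noise, optionally a two-phase mixture;
* **coordinate ensembles** — frames drawn from a multivariate normal over
  residue displacements with a block-structured target correlation, used
  as ground truth for correlation-map and PCA recovery.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .cooperativity import DoseResponse, HillParams
from .dynamics import TrajectoryEnsemble
from .oscillation import Trace
from .protocol import StepProtocol

__all__ = [
    "CellParams",
    "PopulationParams",
    "CovarianceSpec",
    "IP1Assay",
    "simulate_trace",
    "simulate_population",
    "simulate_dose_response",
    "simulate_ip1_assay",
    "simulate_ensemble",
]

# fraction of the inter-spike interval used as uniform timing jitter;
# a near-regular train keeps the recovered peaks/min tight
SPIKE_JITTER_FRACTION = 0.10
# [Ca2+]o above which a step change elicits an initial transient peak
TRANSIENT_CA_THRESHOLD_MM = 0.5
# relative overshoot of the step transient at plateau steps
PLATEAU_OVERSHOOT = 0.05
# earliest spike-train event after a step change, s; keeps the first spike
# clearly separated from the step transient for downstream peak calling
SPIKE_TRAIN_START_MIN_S = 18.0


RateFn = Callable[[float, float], float]


def constant_rate(ppm_without_phe: float, ppm_with_phe: Optional[float] = None) -> RateFn:
    """Spike rate independent of [Ca2+]o, optionally raised by L-Phe."""
    with_phe = ppm_without_phe if ppm_with_phe is None else ppm_with_phe

    def rate(ca_mM: float, phe_mM: float) -> float:
        return with_phe if phe_mM > 0 else ppm_without_phe

    return rate


@dataclass
class CellParams:
    """Generator parameters for one cell's oscillation phenotype."""

    onset_mM: float
    plateau_mM: float
    rate_fn: RateFn
    baseline_ratio: float = 0.30
    spike_amplitude: float = 0.60
    spike_width_s: float = 4.0
    plateau_ratio: float = 1.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not self.onset_mM < self.plateau_mM:
            raise ValueError("onset_mM must be below plateau_mM")
        if self.spike_amplitude <= 0 or self.plateau_ratio <= 0 or self.baseline_ratio <= 0:
            raise ValueError("amplitudes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _gaussian_bump(times: np.ndarray, center: float, amplitude: float, sd: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((times - center) / sd) ** 2)


def simulate_trace(
    params: CellParams,
    protocol: StepProtocol,
    seed: int | np.random.Generator = 0,
    cell_id: str = "cell0",
) -> Trace:
    """Simulate one ratiometric trace under a stepwise protocol.

    The trace records ground truth in ``meta``: the thresholds, the emitted
    spike times per step and whether the cell responded at all.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = protocol.time_grid()
    ratio = np.full(times.size, params.baseline_ratio)
    sd = params.spike_width_s / 2.355  # width interpreted as FWHM
    spike_times: dict[int, list[float]] = {}

    for i, step in enumerate(protocol.steps):
        t0, t1 = protocol.step_window(i)
        at_plateau = step.ca_mM >= params.plateau_mM
        oscillating = params.onset_mM <= step.ca_mM < params.plateau_mM

        if at_plateau:
            # sustained elevation; the step change itself is a rise with a
            # small overshoot that reads as the initial peak
            in_step = (times >= t0) & (times < t1)
            ratio[in_step] = params.plateau_ratio
            ratio += np.where(
                (times >= t0) & (times < t1),
                _gaussian_bump(times, t0 + 4.0, PLATEAU_OVERSHOOT * params.plateau_ratio, sd),
                0.0,
            )
            continue

        if step.ca_mM > TRANSIENT_CA_THRESHOLD_MM:
            ratio += _gaussian_bump(times, t0 + 4.0, params.spike_amplitude, sd)

        if oscillating:
            rate_ppm = params.rate_fn(step.ca_mM, step.phe_mM)
            if rate_ppm > 0:
                isi = 60.0 / rate_ppm
                # first event near half an interval into the step (so the count
                # over the dwell tracks rate * dwell), but never on top of the
                # step transient
                offset = max(0.5 * isi, SPIKE_TRAIN_START_MIN_S)
                margin = 2.0 * sd  # keep the spike apex inside the dwell
                n_max = int(np.ceil((t1 - t0) / isi)) + 1
                jitter = rng.uniform(-SPIKE_JITTER_FRACTION, SPIKE_JITTER_FRACTION, n_max) * isi
                events = t0 + offset + np.arange(n_max) * isi + jitter
                events = events[events < t1 - margin]
                for ev in events:
                    ratio += _gaussian_bump(times, ev, params.spike_amplitude, sd)
                spike_times[i] = [float(e) for e in events]

    if params.noise_sd > 0:
        ratio = ratio + rng.normal(0.0, params.noise_sd, times.size)

    meta = {
        "onset_mM": params.onset_mM,
        "plateau_mM": params.plateau_mM,
        "spike_times": spike_times,
        "responding": bool(spike_times)
        or any(s.ca_mM >= params.plateau_mM for s in protocol.steps),
    }
    return Trace(cell_id=cell_id, times_s=times, ratios=ratio, protocol=protocol, meta=meta)


def _lognormal(rng: np.random.Generator, median: float, cv: float, size=None):
    """Log-normal draw parameterized by its median and coefficient of variation."""
    if cv <= 0:
        return np.full(size, median) if size is not None else median
    sigma = np.sqrt(np.log1p(cv**2))
    return median * np.exp(rng.normal(0.0, sigma, size))


@dataclass
class PopulationParams:
    """Cell-to-cell heterogeneity for a simulated imaging field.

    Onset and plateau thresholds are log-normal across cells (strictly
    positive, right-skewed); a fixed fraction of cells never responds.
    """

    n_cells: int
    onset_median_mM: float
    onset_cv: float
    plateau_median_mM: float
    plateau_cv: float
    rate_fn: RateFn
    fraction_nonresponding: float = 0.0
    cell_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.onset_median_mM <= 0 or self.plateau_median_mM <= 0:
            raise ValueError("threshold medians must be positive")
        if self.onset_cv < 0 or self.plateau_cv < 0:
            raise ValueError("CVs must be non-negative")
        if not 0 <= self.fraction_nonresponding < 1:
            raise ValueError("fraction_nonresponding must be in [0, 1)")


def simulate_population(
    pop: PopulationParams, protocol: StepProtocol, seed: int = 0
) -> tuple[list[Trace], pd.DataFrame]:
    """Simulate an imaging field of heterogeneous cells.

    Returns the traces and a ground-truth table with one row per cell
    (drawn thresholds and the responder label) for recovery tests.
    """
    rng = np.random.default_rng(seed)
    onsets = _lognormal(rng, pop.onset_median_mM, pop.onset_cv, pop.n_cells)
    plateaus = _lognormal(rng, pop.plateau_median_mM, pop.plateau_cv, pop.n_cells)
    # enforce onset < plateau cell-wise (rare inversions under wide CVs)
    bad = plateaus <= onsets
    plateaus[bad] = onsets[bad] * 1.5
    responders = rng.random(pop.n_cells) >= pop.fraction_nonresponding

    max_ca = max(s.ca_mM for s in protocol.steps)
    traces = []
    for i in range(pop.n_cells):
        cid = f"cell{i:03d}"
        if responders[i]:
            cp = CellParams(
                onset_mM=float(onsets[i]),
                plateau_mM=float(plateaus[i]),
                rate_fn=pop.rate_fn,
                **pop.cell_kwargs,
            )
        else:
            # a silent cell: thresholds far above any protocol step
            cp = CellParams(
                onset_mM=max_ca * 100.0,
                plateau_mM=max_ca * 200.0,
                rate_fn=pop.rate_fn,
                **pop.cell_kwargs,
            )
        traces.append(simulate_trace(cp, protocol, seed=rng, cell_id=cid))
    truth = pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in traces],
            "onset_mM": onsets,
            "plateau_mM": plateaus,
            "responding": responders,
        }
    )
    return traces, truth


def simulate_dose_response(
    hp: HillParams | tuple[HillParams, HillParams, float],
    concentrations_mM: Sequence[float],
    noise_cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    readout: str = "ca_i",
    phe_mM: float = 0.0,
) -> DoseResponse:
    """Hill-distributed population readout with multiplicative noise.

    ``hp`` may be a single :class:`HillParams` or a ``(phase1, phase2,
    fraction)`` triple for a biphasic mixture; each replicate response is
    the noiseless curve times ``(1 + eps)`` with ``eps ~ N(0, noise_cv)``.
    """
    conc = np.asarray(concentrations_mM, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(hp, tuple):
        p1, p2, frac = hp
        if not 0 <= frac <= 1:
            raise ValueError("mixture fraction must be in [0, 1]")
        clean = frac * p1.response(conc) + (1.0 - frac) * p2.response(conc)
    else:
        clean = hp.response(conc)
    cc, rr, resp = [], [], []
    for rep in range(replicates):
        eps = rng.normal(0.0, noise_cv, conc.size) if noise_cv > 0 else 0.0
        cc.append(conc)
        rr.append(np.full(conc.size, rep))
        resp.append(clean * (1.0 + eps))
    return DoseResponse(
        np.concatenate(cc),
        np.concatenate(resp),
        np.concatenate(rr),
        readout=readout,
        phe_mM=phe_mM,
    )


@dataclass
class IP1Assay:
    """Raw competition-immunoassay binding values.

    ``unstimulated`` is the IP1-HRP binding with no receptor stimulation;
    ``stimulated[i, j]`` is the binding at concentration i, replicate j.
    The percent-inhibition transform of these values recovers the
    underlying Hill curve.
    """

    concentrations_mM: np.ndarray
    stimulated: np.ndarray
    unstimulated: float

    def to_frame(self) -> pd.DataFrame:
        n_conc, n_rep = self.stimulated.shape
        return pd.DataFrame(
            {
                "conc_mM": np.repeat(self.concentrations_mM, n_rep),
                "replicate": np.tile(np.arange(n_rep), n_conc),
                "stimulated": self.stimulated.ravel(),
                "unstimulated": self.unstimulated,
            }
        )


def simulate_ip1_assay(
    hp: HillParams,
    concentrations_mM: Sequence[float],
    noise_cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    unstimulated_binding: float = 1000.0,
) -> IP1Assay:
    """Simulate raw IP1-HRP binding whose inhibition follows a Hill curve.

    ``hp`` describes the target percent-inhibition curve H(c) (0-100 scale);
    stimulated binding is ``B0 * (1 - H(c)/100)`` with multiplicative noise.
    """
    conc = np.asarray(concentrations_mM, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    h = hp.response(conc)  # percent inhibition, 0..100
    if np.any(h < 0) or np.any(h > 100):
        raise ValueError("percent-inhibition curve must lie in [0, 100]")
    clean = unstimulated_binding * (1.0 - h / 100.0)
    noise = (
        rng.normal(0.0, noise_cv, (conc.size, replicates)) if noise_cv > 0 else 0.0
    )
    stim = clean[:, None] * (1.0 + noise) * np.ones((1, replicates))
    return IP1Assay(conc, stim, unstimulated_binding)


@dataclass
class CovarianceSpec:
    """Block-structured target correlation for a synthetic ensemble.

    ``blocks`` is a list of ``(residues_a, residues_b, correlation)``
    entries; ``variance_A2`` is the per-residue total displacement variance
    (summed over x, y, z). The implied full correlation matrix must be
    positive semi-definite; construction fails naming the first block that
    breaks it.
    """

    n_residues: int
    blocks: list[tuple[Sequence[int], Sequence[int], float]] = field(default_factory=list)
    variance_A2: float | Sequence[float] = 1.0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        v = np.asarray(self.variance_A2, dtype=float)
        if v.ndim == 0:
            v = np.full(self.n_residues, float(v))
        if v.size != self.n_residues or np.any(v <= 0):
            raise ValueError("variance_A2 must be positive, one value per residue")
        self._variances = v
        corr = np.eye(self.n_residues)
        for bi, (a, b, c) in enumerate(self.blocks):
            if not -1.0 <= c <= 1.0:
                raise ValueError(f"block {bi}: correlation {c} outside [-1, 1]")
            a = np.asarray(a, int)
            b = np.asarray(b, int)
            for arr in (a, b):
                if arr.size == 0 or arr.min() < 0 or arr.max() >= self.n_residues:
                    raise ValueError(f"block {bi}: residue indices out of range")
            corr[np.ix_(a, b)] = c
            corr[np.ix_(b, a)] = c
            np.fill_diagonal(corr, 1.0)  # blocks may overlap the diagonal
            eig_min = float(np.linalg.eigvalsh(corr).min())
            if eig_min < -1e-8:
                raise ValueError(
                    f"covariance spec is not positive semi-definite after block {bi} "
                    f"(sets {list(a)} x {list(b)}, correlation {c}): "
                    f"min eigenvalue {eig_min:.3g}"
                )
        self._correlation = corr

    @classmethod
    def coupled_sites(
        cls,
        n_residues: int,
        couplings: Sequence[tuple[Sequence[int], Sequence[int], float]],
        within: float = 0.9,
        variance_A2: float | Sequence[float] = 1.0,
    ) -> "CovarianceSpec":
        """Spec where each coupled pair of sites also moves coherently within
        itself.

        A bare inter-set correlation block is rarely positive semi-definite
        on its own (two residues cannot both track a third while ignoring
        each other), so this constructor adds a within-set correlation of
        ``within`` to every site before the requested cross-correlations.
        """
        blocks: list[tuple[Sequence[int], Sequence[int], float]] = []
        seen: list[tuple[int, ...]] = []
        for a, b, _ in couplings:
            for s in (tuple(a), tuple(b)):
                if s not in seen:
                    seen.append(s)
                    blocks.append((list(s), list(s), within))
        blocks.extend((list(a), list(b), c) for a, b, c in couplings)
        return cls(n_residues, blocks, variance_A2)

    @property
    def variances(self) -> np.ndarray:
        return self._variances

    def correlation_matrix(self) -> np.ndarray:
        return self._correlation.copy()

    def covariance_per_axis(self) -> np.ndarray:
        """Per-axis residue covariance K such that 3*K_ii = variance_A2[i]."""
        s = np.sqrt(self._variances / 3.0)
        return self._correlation * np.outer(s, s)

    def to_dict(self) -> dict:
        return {
            "n_residues": self.n_residues,
            "variance_A2": self._variances.tolist(),
            "blocks": [
                {"set_a": list(map(int, a)), "set_b": list(map(int, b)), "correlation": c}
                for a, b, c in self.blocks
            ],
        }


def reference_geometry(n_residues: int, spacing_A: float = 3.8) -> np.ndarray:
    """A gently curved Calpha-like reference chain (non-collinear)."""
    i = np.arange(n_residues, dtype=float)
    return np.column_stack(
        [spacing_A * i, 2.0 * np.sin(0.5 * i), 2.0 * np.cos(0.3 * i)]
    )


def simulate_ensemble(
    spec: CovarianceSpec, n_frames: int, seed: int = 0
) -> TrajectoryEnsemble:
    """Draw ensemble frames from the specified residue-residue covariance.

    Each Cartesian axis is sampled independently with the per-axis
    covariance implied by the spec, so the isotropic displacement
    correlation between residues equals the spec's block correlations.
    Frames share a common reference frame (no rigid-body motion), so the
    ensemble is returned with ``superposed=True``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    K = spec.covariance_per_axis()
    # eigendecomposition square root (robust to exactly singular specs)
    w, V = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    z = rng.standard_normal((3, n_frames, spec.n_residues))
    disp = np.einsum("afj,ij->fia", z, L)  # frames x residues x 3
    ref = reference_geometry(spec.n_residues)
    coords = ref[None, :, :] + disp
    return TrajectoryEnsemble(
        coords=coords,
        labels=[f"R{i+1}" for i in range(spec.n_residues)],
        superposed=True,
        ground_truth=spec.to_dict(),
    )
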