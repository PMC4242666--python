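"""End-to-end analysis pipeline: simulate -> extract -> fit -> report.

``run_pipeline`` chains the synthetic generators, the oscillation feature
extraction and the Hill fitting for one construct preset (and optionally an
ensemble-dynamics block), writing a JSON report plus CSV tables and
figures. Reports contain no timestamps, so a rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .cooperativity import (
    BiphasicHillModel,
    HillModel,
    heterotropic_shift,
    ip1_percent_inhibition,
    normalize_to_max,
    select_model,
    DoseResponse,
)
from .dynamics import compute_dccm, site_coupling, trajectory_pca
from .io import write_traces
from .oscillation import PeakConfig, analyze_trace, features_to_frame, summarize_population
from .presets import get_preset
from .synthdata import (
    CovarianceSpec,
    simulate_dose_response,
    simulate_ensemble,
    simulate_ip1_assay,
    simulate_population,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    preset: str = "WT"
    seed: int = 0
    n_cells: int = 50
    dwell_s: float = 180.0
    sampling_dt_s: float = 1.0
    fraction_nonresponding: float = 0.1
    replicates: int = 3
    noise_cv: float = 0.05
    readouts: tuple[str, ...] = ("ca_i", "ip1", "perk", "phe_response")
    dynamics: Optional[dict] = None
    outdir: Path = Path("casr_run")
    make_figures: bool = True
    peak_config: PeakConfig = field(default_factory=PeakConfig)

    def __post_init__(self) -> None:
        get_preset(self.preset)  # validate early
        self.seed = int(self.seed)
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        peak_cfg = PeakConfig(**payload.pop("peak_config", {}))
        if "readouts" in payload:
            payload["readouts"] = tuple(payload["readouts"])
        return cls(peak_config=peak_cfg, **payload)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        blob = json.dumps(
            {
                k: v
                for k, v in self.__dict__.items()
                if k not in ("peak_config", "outdir", "make_figures")
            }
            | {"peak_config": vars(self.peak_config)},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(base: int, offset: int) -> int:
    return (base * 1009 + offset) % (2**31 - 1)


def _oscillation_stage(cfg: RunConfig, outdir: Path) -> dict:
    preset = get_preset(cfg.preset)
    section = {}
    for with_phe, key in ((False, "no_phe"), (True, "with_phe")):
        protocol = preset.protocol(with_phe, cfg.dwell_s, cfg.sampling_dt_s)
        pop = preset.population_params(
            cfg.n_cells, with_phe, cfg.fraction_nonresponding
        )
        seed = _stage_seed(cfg.seed, 1 + int(with_phe))
        traces, truth = simulate_population(pop, protocol, seed=seed)
        features = [
            analyze_trace(t, freq_at_mM=preset.freq_at_mM, cfg=cfg.peak_config)
            for t in traces
        ]
        edges = [0.0] + [s.ca_mM for s in protocol.steps]
        summary = summarize_population(features, edges)
        write_traces(traces, outdir / f"traces_{key}.csv")
        protocol.to_json(outdir / f"protocol_{key}.json")
        features_to_frame(features).to_csv(outdir / f"features_{key}.csv", index=False)
        section[key] = {
            "seed": seed,
            "summary": summary.to_dict(),
            "modal_start_mM": summary.modal_start_mM(),
            "modal_end_mM": summary.modal_end_mM(),
            "start_modal_fraction": summary.start_modal_fraction(),
        }
        if cfg.make_figures:
            _histogram_figure(summary, outdir / f"oscillation_{key}.png")
    return section


def _fit_readout(cfg: RunConfig, readout: str, with_phe: bool, seed: int):
    """Simulate one readout for the configured preset and fit it."""
    preset = get_preset(cfg.preset)
    phe_mM = 5.0 if with_phe else 0.0
    if readout == "ca_i":
        truth = (
            (preset.cai_biphasic_phe if with_phe else preset.cai_biphasic)
            if preset.cai_biphasic is not None
            else (preset.cai_phe if with_phe else preset.cai)
        )
        dr = simulate_dose_response(
            truth,
            preset.dose_conc_mM,
            cfg.noise_cv,
            cfg.replicates,
            seed,
            readout="ca_i",
            phe_mM=phe_mM,
        )
        dr = normalize_to_max(dr)
    elif readout == "ip1":
        assay = simulate_ip1_assay(
            preset.ip1_hill(with_phe),
            preset.ip1_conc_mM,
            cfg.noise_cv,
            cfg.replicates,
            seed,
        )
        pct = ip1_percent_inhibition(assay.stimulated, assay.unstimulated)
        n_conc, n_rep = pct.shape
        dr = DoseResponse(
            np.repeat(assay.concentrations_mM, n_rep),
            pct.ravel(),
            np.tile(np.arange(n_rep), n_conc),
            readout="ip1",
            phe_mM=phe_mM,
        )
    elif readout == "perk":
        dr = simulate_dose_response(
            preset.erk_hill(with_phe),
            preset.erk_conc_mM,
            cfg.noise_cv,
            cfg.replicates,
            seed,
            readout="perk",
            phe_mM=phe_mM,
        )
    elif readout == "phe_response":
        if with_phe:
            return None, None
        dr = simulate_dose_response(
            preset.phe_hill(),
            preset.phe_conc_mM,
            cfg.noise_cv,
            cfg.replicates,
            seed,
            readout="phe_response",
        )
    else:
        raise ValueError(f"unknown readout {readout!r}")

    mono = HillModel(dr).fit()
    entry = {"seed": seed, "hill": mono.to_dict()}
    if readout == "ca_i" and get_preset(cfg.preset).cai_biphasic is not None:
        bi = BiphasicHillModel(dr).fit()
        entry["biphasic"] = bi.to_dict()
        entry["selected_model"] = select_model(mono, bi)
    return entry, mono


def _cooperativity_stage(cfg: RunConfig, outdir: Path) -> dict:
    section = {}
    for r_i, readout in enumerate(cfg.readouts):
        fits = {}
        mono_fits = {}
        for with_phe, key in ((False, "no_phe"), (True, "with_phe")):
            seed = _stage_seed(cfg.seed, 10 + 2 * r_i + int(with_phe))
            entry, mono = _fit_readout(cfg, readout, with_phe, seed)
            if entry is None:
                continue
            fits[key] = entry
            mono_fits[key] = mono
        if {"no_phe", "with_phe"} <= set(mono_fits):
            shift = heterotropic_shift(mono_fits["no_phe"], mono_fits["with_phe"])
            fits["phe_shift"] = shift.to_dict()
        section[readout] = fits
    return section


def _dynamics_stage(cfg: RunConfig, outdir: Path) -> dict:
    dyn = cfg.dynamics or {}
    spec = CovarianceSpec(
        n_residues=int(dyn.get("n_residues", 30)),
        blocks=[
            (b["set_a"], b["set_b"], float(b["correlation"]))
            for b in dyn.get("blocks", [])
        ],
        variance_A2=dyn.get("variance_A2", 1.0),
    )
    seed = _stage_seed(cfg.seed, 50)
    ens = simulate_ensemble(spec, int(dyn.get("n_frames", 2000)), seed=seed)
    cmap = compute_dccm(ens)
    cmap.to_csv(outdir / "dccm.csv")
    out = {"seed": seed, "n_frames": ens.n_frames, "n_residues": ens.n_residues}
    sites = {k: list(map(int, v)) for k, v in dyn.get("sites", {}).items()}
    couplings = {}
    for pair in dyn.get("couplings", []):
        a, b = pair["a"], pair["b"]
        couplings[f"{a}~{b}"] = site_coupling(
            cmap, sites[a], sites[b], threshold=float(pair.get("threshold", 0.5))
        ).to_dict()
    if couplings:
        out["site_couplings"] = couplings
    pca = trajectory_pca(ens, k=int(dyn.get("modes", 3)))
    out["pca"] = pca.to_dict()
    np.savetxt(
        outdir / "pca_projections.csv",
        pca.projections,
        delimiter=",",
        header=",".join(f"mode{i+1}" for i in range(pca.projections.shape[1])),
        comments="",
    )
    return out


def _histogram_figure(summary, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    centers = summary.bin_edges_mM[1:]
    width = np.diff(summary.bin_edges_mM)
    for ax, hist, title in (
        (axes[0], summary.start_hist, "starting point"),
        (axes[1], summary.end_hist, "ending point"),
    ):
        ax.bar(centers, hist, width=0.8 * width, align="center", color="0.4")
        ax.set_xlabel("[Ca$^{2+}$]$_o$ (mM)")
        ax.set_ylabel("cells")
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis for one construct and write the report.

    Stages run in order (oscillation, cooperativity, optional dynamics);
    a failing stage aborts with its name while earlier outputs remain on
    disk.
    """
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "preset": cfg.preset,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
    }
    stages = [("oscillation", _oscillation_stage), ("cooperativity", _cooperativity_stage)]
    if cfg.dynamics is not None:
        stages.append(("dynamics", _dynamics_stage))
    for name, stage in stages:
        try:
            report[name] = stage(cfg, outdir)
        except Exception as exc:  # partial outputs stay on disk
            (outdir / "report_partial.json").write_text(
                json.dumps(report, indent=2, sort_keys=True)
            )
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
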