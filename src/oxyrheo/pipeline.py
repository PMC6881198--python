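"""End-to-end pipeline driver: traces -> rheograms -> fits -> cohort statistics.

`run_pipeline` orchestrates the full analysis that the device produces for
a patient cohort: per-patient rheogram inversion at each oxygen tension,
power-law fits (flow behavior index n, consistency K, goodness of fit),
Friedman repeated-measures testing of n across oxygen tensions with
Bonferroni post-hoc pairs, and — when the schedule includes both ambient
(160 mm Hg) and anoxic tensions — the fractional velocity change metric.
Every run writes a manifest with the seed, config hash and package
version; the same config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import (
    blood_params_from_config,
    cohort_spec_from_config,
    config_hash,
    inversion_settings_from_config,
    network_from_config,
    validate_config,
)
from .device import FluidState, reynolds_number
from .io import write_fit_report, write_json, write_rheogram, write_trace
from .rheofit import PowerLawFit, fit_power_law, fractional_velocity_change
from .stats import PairedCohortTable, friedman_test, pairwise_bonferroni
from .synthetic import generate_cohort
from .viscometry import InversionSettings, Rheogram, RheologyTrace, infer_rheogram

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "analyze_traces", "fit_rheograms"]

BLOOD_DENSITY_KG_M3 = 1060.0


@dataclass
class PipelineResult:
    rheograms: Dict[str, Dict[float, Rheogram]]
    fits: Dict[str, List[PowerLawFit]]
    cohort_table: Optional[PairedCohortTable]
    stats_report: Optional[dict]
    velocity_response: Optional[pd.DataFrame]
    manifest: dict

    def mean_n_by_tension(self) -> Dict[float, float]:
        """Cohort mean flow behavior index per oxygen tension."""
        acc: Dict[float, List[float]] = {}
        for fits in self.fits.values():
            for f in fits:
                acc.setdefault(f.po2_mmhg, []).append(f.n)
        return {po2: float(np.mean(v)) for po2, v in sorted(acc.items())}


def fit_rheograms(rheograms: Dict[float, Rheogram]) -> List[PowerLawFit]:
    """Power-law fit of each oxygen tension's stress/shear-rate curve."""
    fits = []
    for po2 in sorted(rheograms, reverse=True):
        r = rheograms[po2]
        fits.append(fit_power_law(r.shear_rates, r.stresses, po2_mmhg=po2))
    return fits


def _velocity_response(traces: Sequence[RheologyTrace], settings: InversionSettings) -> Optional[pd.DataFrame]:
    """Fractional velocity change per sample, if ambient and anoxic data exist.

    Uses the steady-state mean velocity at the highest shared pressure step.
    """
    rows = []
    for trace in traces:
        tensions = trace.oxygen_tensions()
        if not (0.0 in tensions and any(t >= 150.0 for t in tensions)):
            return None
        hi = max(t for t in tensions if t >= 150.0)
        p_shared = min(
            trace.steps(hi)["pressure_pa"].max(), trace.steps(0.0)["pressure_pa"].max()
        )

        def steady_u(po2: float) -> float:
            grp = trace.steps(po2)
            grp = grp[grp["pressure_pa"] == p_shared]
            t0, t1 = grp["time_s"].min(), grp["time_s"].max()
            cutoff = t0 + (1 - settings.steady_state_fraction) * (t1 - t0)
            kept = grp[grp["time_s"] >= cutoff]
            return float(kept["umax_um_s"].mean())

        v_ox, v_deox = steady_u(hi), steady_u(0.0)
        rows.append(
            {
                "sample_id": trace.sample_id,
                "v_oxygenated_um_s": v_ox,
                "v_deoxygenated_um_s": v_deox,
                "fractional_velocity_change": fractional_velocity_change(v_ox, v_deox),
            }
        )
    return pd.DataFrame(rows)


def analyze_traces(
    traces: Sequence[RheologyTrace],
    network,
    settings: InversionSettings,
    alpha: float = 0.05,
    posthoc: str = "sign_permutation",
) -> PipelineResult:
    """Run inversion, fitting and cohort statistics on a set of traces."""
    rheograms: Dict[str, Dict[float, Rheogram]] = {}
    fits: Dict[str, List[PowerLawFit]] = {}
    for trace in traces:
        rheo = infer_rheogram(trace, network, settings)
        rheograms[trace.sample_id] = rheo
        fits[trace.sample_id] = fit_rheograms(rheo)

    cohort_table = None
    stats_report = None
    tensions = sorted({f.po2_mmhg for fl in fits.values() for f in fl}, reverse=True)
    if len(traces) >= 2 and len(tensions) >= 2:
        values = np.array(
            [
                [next(f.n for f in fits[t.sample_id] if f.po2_mmhg == po2) for po2 in tensions]
                for t in traces
            ]
        )
        cohort_table = PairedCohortTable.from_arrays(
            values,
            condition_labels=tensions,
            patient_ids=[t.sample_id for t in traces],
        )
        fr = friedman_test(cohort_table)
        pairs = pairwise_bonferroni(cohort_table, alpha=alpha, method=posthoc)
        stats_report = {
            "metric": "flow_behavior_index",
            "conditions_mmhg": list(tensions),
            "friedman": fr.to_dict(),
            "pairwise_bonferroni": [p.to_dict() for p in pairs],
            "alpha": alpha,
        }

    velocity_response = _velocity_response(traces, settings)
    return PipelineResult(
        rheograms=rheograms,
        fits=fits,
        cohort_table=cohort_table,
        stats_report=stats_report,
        velocity_response=velocity_response,
        manifest={},
    )


def run_pipeline(
    config: dict,
    out_dir: Optional[str] = None,
    traces: Optional[Sequence[RheologyTrace]] = None,
    synthetic: bool = False,
    seed: Optional[int] = None,
    write_figures: bool = False,
) -> PipelineResult:
    """Full pipeline: (generate or accept) traces, invert, fit, test, write outputs.

    Deterministic given (config, seed).  With ``synthetic=True`` a cohort is
    generated from the config's generator block; otherwise ``traces`` must be
    supplied.  Outputs (per-sample rheogram CSVs and fit JSONs, cohort stats
    JSON, velocity-response CSV, manifest) go to ``out_dir`` when given.
    """
    cfg = validate_config(config, require_seed=synthetic and seed is None)
    network = network_from_config(cfg)
    settings = inversion_settings_from_config(cfg)
    used_seed = seed if seed is not None else cfg["generator"].get("seed")

    truth = None
    if synthetic:
        params = blood_params_from_config(cfg)
        spec = cohort_spec_from_config(cfg, seed=used_seed)
        base_model = params.sickle_model()
        traces, truth = generate_cohort(spec, base_model=base_model, network=network, settings=settings)
    elif traces is None:
        raise ValueError("run_pipeline needs input traces unless synthetic=True")

    # laminar-flow sanity check at the fastest observed velocity
    u_max = max(float(t.records["umax_um_s"].max()) for t in traces) * 1e-6
    geo = network.experimental.geometry
    if geo is not None and u_max > 0:
        eta_ref = 0.004
        re = reynolds_number(
            FluidState(BLOOD_DENSITY_KG_M3, eta_ref, u_max), geo.height_m
        )
        if re >= 1:
            logger.warning("Reynolds number %.3g >= 1: resistor model assumptions violated", re)

    result = analyze_traces(
        traces,
        network,
        settings,
        alpha=cfg["stats"]["alpha"],
        posthoc=cfg["stats"]["posthoc"],
    )
    result.manifest = {
        "package": "oxyrheo",
        "version": __version__,
        "config_sha256_16": config_hash(cfg),
        "seed": used_seed,
        "n_samples": len(traces),
        "synthetic": bool(synthetic),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for trace in traces:
            if synthetic:
                write_trace(trace, out / f"trace_{trace.sample_id}.csv")
            write_rheogram(
                list(result.rheograms[trace.sample_id].values()),
                out / f"rheogram_{trace.sample_id}.csv",
            )
            write_fit_report(result.fits[trace.sample_id], out / f"fits_{trace.sample_id}.json")
        if result.stats_report is not None:
            write_json(result.stats_report, out / "cohort_stats.json")
        if result.velocity_response is not None:
            result.velocity_response.to_csv(out / "velocity_response.csv", index=False)
        if truth is not None:
            write_json(truth, out / "ground_truth.json")
        summary = {
            "mean_flow_behavior_index": {
                str(k): v for k, v in result.mean_n_by_tension().items()
            }
        }
        write_json({**result.manifest, **summary}, out / "manifest.json")
        if write_figures:
            from .plotting import plot_cohort_rheograms

            plot_cohort_rheograms(result, out / "rheograms.png")
    return result
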