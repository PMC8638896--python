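"""End-to-end experiment drivers: the three in-silico experiments.

Each driver builds blueprints and ensemble specs from a small set of knobs,
runs the Monte Carlo ensembles, and returns an :class:`ExperimentResult`
holding a tidy summary table, the full per-parameter-set similarity reports
(so distribution/violin plots can be regenerated), and a manifest sufficient
for a bit-identical rerun.

Per-condition seeds are derived from the master seed with
``numpy.random.SeedSequence([master_seed, condition_index])`` reduced below
2**31, so conditions are independent and the whole experiment is reproducible
from ``(config, seed)`` alone.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .sampling import CommunityBlueprint, EnsembleSpec
from .simulate import SolverControl, run_ensemble
from .similarity import PATTERN_THRESHOLD, SimilarityReport, summarize_ensemble

__all__ = ["ExperimentResult", "condition_seed", "run_essential_sweep",
           "run_concentration_experiment", "run_richness_sweep",
           "DEFAULT_ESSENTIAL_VALUES", "DEFAULT_SUPPLY_VALUES",
           "DEFAULT_RICHNESS_VALUES", "UNIFORM_SUPPLY", "SECRETION_FRACTION"]

log = logging.getLogger(__name__)

DEFAULT_ESSENTIAL_VALUES: tuple[int | str, ...] = (0, 5, 10, 20, "all")
DEFAULT_SUPPLY_VALUES: tuple[float, ...] = (100.0, 1.0)
DEFAULT_RICHNESS_VALUES: tuple[int, ...] = (2, 5, 10)
#: Supply concentration for the uniform-layout experiments (the bounded,
#: selective regime; see docs/methods.md).
UNIFORM_SUPPLY = 1.0
#: Fraction of consumed flux returned as byproducts in the study conditions.
SECRETION_FRACTION = 0.8


def condition_seed(master_seed: int, index: int) -> int:
    """Deterministic per-condition seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


@dataclass
class ExperimentResult:
    """Summary table + full reports + rerun manifest for one experiment."""

    name: str
    table: pd.DataFrame
    reports: dict[str, SimilarityReport]
    manifest: dict

    def write(self, out_dir: str | Path) -> Path:
        """Write summary CSV, per-pair distributions, JSON summary, manifest.

        Returns the output directory.  Layout::

            <out>/summary.csv          one row per condition
            <out>/pairs.csv            one row per (condition, set, pair)
            <out>/summary.json         machine-readable condition summaries
            <out>/manifest.json        config + versions for bit-identical rerun
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "summary.csv", index=False)
        frames = []
        for cond, rep in self.reports.items():
            f = rep.to_frame()
            f.insert(0, "condition", cond)
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(out / "pairs.csv",
                                                    index=False)
        (out / "summary.json").write_text(json.dumps(
            {cond: rep.summary() for cond, rep in self.reports.items()},
            indent=2))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return out


def _manifest(name: str, seed: int, spec: EnsembleSpec,
              control: SolverControl, extra: dict) -> dict:
    return {
        "experiment": name,
        "master_seed": int(seed),
        "n_param_sets": spec.n_param_sets,
        "n_replicates": spec.n_replicates,
        "init_biomass_range": list(spec.init_biomass_range),
        "mu": spec.mu,
        "sigma": spec.sigma,
        "solver": asdict(control),
        "secretion_fraction": SECRETION_FRACTION,
        "pattern_threshold": PATTERN_THRESHOLD,
        "versions": {
            "assemblysim": _pkg_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        **extra,
    }


def _summary_row(rep: SimilarityReport) -> dict:
    return {
        "mean_similarity": rep.mean,
        "sd_similarity": rep.sd,
        "n_pairs": int(rep.pooled.size),
        "n_param_sets": len(rep.per_set_pairs),
        "n_dropped_sets": rep.n_dropped_sets,
        "pattern_probability": rep.pattern_probability,
    }


def run_essential_sweep(
        n_essential_values=DEFAULT_ESSENTIAL_VALUES,
        spec: EnsembleSpec = EnsembleSpec(),
        control: SolverControl = SolverControl(),
        supply: float = UNIFORM_SUPPLY,
        progress: bool = False) -> ExperimentResult:
    """Sweep the number of essential symbionts in the uniform community.

    10 resources x 10 specialists each, no concentration specialisation
    (G = 1).  For each value in ``n_essential_values`` (ints or ``"all"``)
    the full ensemble is run and pooled pairwise similarities aggregated.
    """
    blueprint = CommunityBlueprint.uniform(
        supply_conc_value=supply, secretion_fraction=SECRETION_FRACTION)
    rows, reports = [], {}
    for idx, ne in enumerate(n_essential_values):
        cspec = replace(spec, n_essential=ne,
                        seed=condition_seed(spec.seed, idx))
        ens = run_ensemble(blueprint, cspec, control, progress=progress)
        rep = summarize_ensemble(ens.composition_groups)
        cond = f"n_essential={ne}"
        reports[cond] = rep
        rows.append({"condition": cond, "n_essential": ne,
                     "seed": cspec.seed, **_summary_row(rep)})
    table = pd.DataFrame(rows)
    manifest = _manifest("essential_sweep", spec.seed, spec, control,
                         {"n_essential_values": list(n_essential_values),
                          "supply": supply})
    return ExperimentResult("essential_sweep", table, reports, manifest)


def _is_agreement(adapted: str, supply: float,
                  blueprint: CommunityBlueprint) -> bool:
    """Supply closer (log scale) to the majority's adapted concentration."""
    L_major = blueprint.L_high if adapted == "high" else blueprint.L_low
    L_minor = blueprint.L_low if adapted == "high" else blueprint.L_high
    d_major = abs(np.log(supply) - np.log(L_major))
    d_minor = abs(np.log(supply) - np.log(L_minor))
    return bool(d_major <= d_minor)


def run_concentration_experiment(
        adapted_values: tuple[Literal["high", "low"], ...] = ("high", "low"),
        supplied_I_values=DEFAULT_SUPPLY_VALUES,
        spec: EnsembleSpec = EnsembleSpec(),
        control: SolverControl = SolverControl(),
        progress: bool = False) -> ExperimentResult:
    """Adapted-vs-supplied concentration experiment.

    Communities adapted to a high (45 of 50 supplied-resource specialists
    with L=100) or low (45 with L=1) concentration are supplied each
    concentration in ``supplied_I_values``.  Conditions are labelled
    agreement/disagreement by whether the supply matches the majority's
    adapted concentration; pattern probabilities are reported per condition
    and pooled over the agreement and disagreement groups.
    """
    rows, reports = [], {}
    pooled_flags: dict[str, list[bool]] = {"agreement": [], "disagreement": []}
    idx = 0
    for adapted in adapted_values:
        for supply in supplied_I_values:
            blueprint = CommunityBlueprint.concentration_adapted(
                adapted, supply_conc_value=float(supply),
                secretion_fraction=SECRETION_FRACTION)
            cspec = replace(spec, seed=condition_seed(spec.seed, idx))
            idx += 1
            ens = run_ensemble(blueprint, cspec, control, progress=progress)
            rep = summarize_ensemble(ens.composition_groups)
            kind = ("agreement" if _is_agreement(adapted, supply, blueprint)
                    else "disagreement")
            pooled_flags[kind].extend(rep.pattern_flags)
            cond = f"adapted={adapted},I={supply:g}"
            reports[cond] = rep
            rows.append({"condition": cond, "adapted": adapted,
                         "supply": float(supply), "kind": kind,
                         "seed": cspec.seed, **_summary_row(rep)})
    table = pd.DataFrame(rows)
    pooled = {kind: (float(np.mean(flags)) if flags else float("nan"))
              for kind, flags in pooled_flags.items()}
    manifest = _manifest("concentration", spec.seed, spec, control,
                         {"adapted_values": list(adapted_values),
                          "supplied_I_values": [float(v)
                                                for v in supplied_I_values],
                          "pooled_pattern_probability": pooled})
    return ExperimentResult("concentration", table, reports, manifest)


def run_richness_sweep(
        specialists_values=DEFAULT_RICHNESS_VALUES,
        spec: EnsembleSpec = EnsembleSpec(),
        control: SolverControl = SolverControl(),
        supply: float = UNIFORM_SUPPLY,
        progress: bool = False) -> ExperimentResult:
    """Species-richness sweep: k specialists per resource, G = 1.

    ``n_essential`` follows ``spec`` (default 10) but is capped at the
    other-resource specialist pool for small communities, with a logged
    warning.
    """
    rows, reports = [], {}
    for idx, k in enumerate(specialists_values):
        blueprint = CommunityBlueprint.uniform(
            specialists_per_resource=int(k), supply_conc_value=supply,
            secretion_fraction=SECRETION_FRACTION)
        ne = spec.n_essential
        pool = (blueprint.n_resources - 1) * int(k)
        if ne != "all" and ne > pool:
            log.warning("k=%d: n_essential=%s exceeds the other-resource "
                        "pool (%d); using %d", k, ne, pool, pool)
            ne = pool
        cspec = replace(spec, n_essential=ne,
                        seed=condition_seed(spec.seed, idx))
        ens = run_ensemble(blueprint, cspec, control, progress=progress)
        rep = summarize_ensemble(ens.composition_groups)
        cond = f"k={k}"
        reports[cond] = rep
        rows.append({"condition": cond, "specialists_per_resource": int(k),
                     "n_species": blueprint.n_species, "n_essential": ne,
                     "seed": cspec.seed, **_summary_row(rep)})
    table = pd.DataFrame(rows)
    manifest = _manifest("richness_sweep", spec.seed, spec, control,
                         {"specialists_values": [int(v)
                                                 for v in specialists_values],
                          "supply": supply})
    return ExperimentResult("richness_sweep", table, reports, manifest)
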