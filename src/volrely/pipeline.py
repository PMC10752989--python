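"""Study-mode orchestration: accuracy, test-retest and longitudinal analyses.

Each ``run_*`` function takes a canonical volume table plus a
:class:`PipelineConfig` and returns a plain-dict report (JSON-serializable,
deterministically ordered) echoing the configuration for provenance. The
three modes mirror the three evaluation designs:

* accuracy — predicted vs manual volumes: VPE distributions per method with
  Table-style summaries, Pearson CC with bands, and pairwise method
  comparisons (gated location test on |VPE|, F-test on VPE variances,
  Fisher z on CCs);
* test-retest — two sessions per subject: consistency ICC with 95% CI and
  band, per-subject VPD with median/IQR and the share below 2%, pairwise
  gated location tests on VPD and CI-overlap decisions on ICC;
* longitudinal — BLME fits per method with tau, sigma and the variance
  ratio r = tau/sigma, and pairwise CI-overlap decisions.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .blme import BLMESpec, fit_blme, normalize_time
from .inference import (
    ci_overlap_significant,
    fisher_z_test,
    paired_location_test,
    variance_f_test,
)
from .metrics import icc_consistency, pearson_cc, vpd, vpe, vpe_summary
from .simulate import SimulationConfig, simulate_longitudinal

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_accuracy",
    "run_testretest",
    "run_longitudinal",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, filters and sub-configurations for one pipeline run.

    Defaults reproduce the evaluation protocol's thresholds: p < 0.01 for
    the location/variance/correlation tests, p < 0.05 for the normality
    gate, 95% intervals throughout.
    """

    mode: str = "accuracy"
    alpha_tests: float = 0.01
    alpha_normality: float = 0.05
    alpha_icc: float = 0.05
    gt_method: str = "manual"
    absolute_vpe: bool = True
    rois: tuple[str, ...] | None = None
    methods: tuple[str, ...] | None = None
    seed: int = 0
    blme: BLMESpec = field(default_factory=BLMESpec)
    simulation: SimulationConfig | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "blme" in data and isinstance(data["blme"], dict):
            data["blme"] = BLMESpec(**data["blme"])
        if "simulation" in data and isinstance(data["simulation"], dict):
            data["simulation"] = SimulationConfig(**data["simulation"])
        for key in ("rois", "methods"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def echo(self) -> dict:
        out = asdict(self)
        if self.simulation is not None:
            out["simulation"].pop("timepoints", None)
        return out


def _provenance(config: PipelineConfig, mode: str) -> dict:
    return {"mode": mode, "seed": config.seed, "version": __version__, "config": config.echo()}


def _filtered(table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    if config.rois is not None:
        table = table[table["roi"].isin(config.rois)]
    if config.methods is not None:
        keep = set(config.methods) | {config.gt_method}
        table = table[table["method"].isin(keep)]
    if table.empty:
        raise ValueError("no records left after roi/method filtering")
    return table


def run_simulate(config: PipelineConfig) -> pd.DataFrame:
    """Generate a longitudinal volume table from the config's simulation block."""
    if config.simulation is None:
        raise ValueError("simulate mode requires a 'simulation' configuration block")
    return simulate_longitudinal(config.simulation)


def run_accuracy(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Accuracy study: VPE and CC per method against the ground-truth method."""
    table = _filtered(table, config)
    gt = config.gt_method
    if gt not in set(table["method"]):
        raise ValueError(f"ground-truth method {gt!r} not present in the table")
    gt_tab = table[table["method"] == gt]
    methods = sorted(m for m in table["method"].unique() if m != gt)
    if not methods:
        raise ValueError("no comparison method present")

    warnings: list[str] = []
    per_method = {}
    vpe_lists: dict[tuple[str, str], pd.Series] = {}
    cc_by: dict[tuple[str, str], tuple[float, int]] = {}
    for roi in sorted(table["roi"].unique()):
        gt_roi = gt_tab[gt_tab["roi"] == roi].set_index("subject_id")["volume"]
        for m in methods:
            pred = table[(table["method"] == m) & (table["roi"] == roi)].set_index("subject_id")["volume"]
            common = gt_roi.index.intersection(pred.index)
            dropped = sorted(set(gt_roi.index).symmetric_difference(pred.index))
            if dropped:
                warnings.append(
                    f"{m}/{roi}: excluded {len(dropped)} unmatched subject(s): "
                    + ", ".join(dropped[:10])
                )
            if len(common) < 3:
                raise ValueError(f"{m}/{roi}: fewer than 3 matched subjects")
            v_gt = gt_roi.loc[common]
            v_pred = pred.loc[common]
            errs = pd.Series(vpe(v_pred.to_numpy(), v_gt.to_numpy()), index=common)
            r, band = pearson_cc(v_pred.to_numpy(), v_gt.to_numpy())
            vpe_lists[(m, roi)] = errs
            cc_by[(m, roi)] = (r, len(common))
            per_method[f"{m}/{roi}"] = {
                "n": int(len(common)),
                "vpe": vpe_summary(errs.to_numpy()).as_dict(),
                "cc": r,
                "cc_band": band,
            }

    comparisons = []
    for roi in sorted(table["roi"].unique()):
        for m1, m2 in itertools.combinations(methods, 2):
            e1, e2 = vpe_lists[(m1, roi)], vpe_lists[(m2, roi)]
            common = e1.index.intersection(e2.index)
            a, b = e1.loc[common].to_numpy(), e2.loc[common].to_numpy()
            if config.absolute_vpe:
                loc = paired_location_test(np.abs(a), np.abs(b), config.alpha_tests, config.alpha_normality)
            else:
                loc = paired_location_test(a, b, config.alpha_tests, config.alpha_normality)
            var = variance_f_test(a, b, config.alpha_tests)
            (r1, n1), (r2, n2) = cc_by[(m1, roi)], cc_by[(m2, roi)]
            fz = fisher_z_test(r1, n1, r2, n2, config.alpha_tests)
            comparisons.append(
                {
                    "roi": roi,
                    "method_a": m1,
                    "method_b": m2,
                    "location": loc.as_dict(),
                    "variance": var.as_dict(),
                    "cc": fz.as_dict(),
                }
            )

    report = _provenance(config, "accuracy")
    report.update({"per_method": per_method, "comparisons": comparisons, "warnings": warnings})
    return report


def _session_matrix(sub: pd.DataFrame, key: str) -> pd.DataFrame:
    counts = sub.groupby("subject_id")["session"].nunique()
    rows = sub.groupby("subject_id").size()
    bad = sorted(counts.index[(counts != 2) | (rows != 2)])
    if bad:
        raise ValueError(f"{key}: need exactly two sessions per subject; offending: {', '.join(map(str, bad))}")
    sessions = sorted(sub["session"].unique())
    if len(sessions) != 2:
        raise ValueError(f"{key}: expected exactly two session labels, got {sessions}")
    if set(sessions) == {"test", "retest"}:
        sessions = ["test", "retest"]
    wide = sub.pivot(index="subject_id", columns="session", values="volume")[sessions]
    return wide


def run_testretest(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Test-retest study: ICC and VPD per method, with pairwise comparisons."""
    table = _filtered(table, config)
    methods = sorted(table["method"].unique())
    per_method = {}
    vpd_lists: dict[tuple[str, str], pd.Series] = {}
    icc_by: dict[tuple[str, str], object] = {}
    for roi in sorted(table["roi"].unique()):
        for m in methods:
            sub = table[(table["method"] == m) & (table["roi"] == roi)]
            if sub.empty:
                continue
            wide = _session_matrix(sub, f"{m}/{roi}")
            icc = icc_consistency(wide.to_numpy(), alpha=config.alpha_icc)
            diffs = pd.Series(
                vpd(wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy()), index=wide.index
            )
            q25, med, q75 = np.percentile(diffs, [25, 50, 75])
            per_method[f"{m}/{roi}"] = {
                "n": int(len(wide)),
                "icc": icc.as_dict(),
                "vpd_median": float(med),
                "vpd_iqr": [float(q25), float(q75)],
                "vpd_pct_below_2": float(100.0 * np.mean(diffs < 2.0)),
            }
            vpd_lists[(m, roi)] = diffs
            icc_by[(m, roi)] = icc

    comparisons = []
    for roi in sorted(table["roi"].unique()):
        avail = [m for m in methods if (m, roi) in icc_by]
        for m1, m2 in itertools.combinations(avail, 2):
            d1, d2 = vpd_lists[(m1, roi)], vpd_lists[(m2, roi)]
            common = d1.index.intersection(d2.index)
            loc = paired_location_test(
                d1.loc[common].to_numpy(), d2.loc[common].to_numpy(),
                config.alpha_tests, config.alpha_normality,
            )
            i1, i2 = icc_by[(m1, roi)], icc_by[(m2, roi)]
            sig = ci_overlap_significant(
                i1.estimate, (i1.ci_low, i1.ci_high), i2.estimate, (i2.ci_low, i2.ci_high)
            )
            comparisons.append(
                {
                    "roi": roi,
                    "method_a": m1,
                    "method_b": m2,
                    "vpd_location": loc.as_dict(),
                    "icc_overlap_significant": bool(sig),
                }
            )

    report = _provenance(config, "testretest")
    report.update({"per_method": per_method, "comparisons": comparisons, "warnings": []})
    return report


def run_longitudinal(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Longitudinal study: per-method BLME fits and CI-overlap decisions.

    Returns the report dict; fitted posteriors are attached under the
    non-serialized key ``"_posteriors"`` so callers can export draws.
    """
    table = _filtered(table, config)
    table = normalize_time(table)
    combos = sorted(set(zip(table["method"], table["roi"])))
    posteriors = {}
    per_method = {}
    for i, (m, roi) in enumerate(combos):
        sub = table[(table["method"] == m) & (table["roi"] == roi)]
        spec = replace(config.blme, seed=(config.blme.seed * 100003 + 7919 * i) % 2**31)
        post = fit_blme(sub, spec)
        posteriors[(m, roi)] = post
        s = post.summaries
        per_method[f"{m}/{roi}"] = {
            "n_subjects": len(post.subjects),
            "n_obs": post.n_obs,
            "r": s["r"],
            "tau": s["tau"],
            "sigma": s["sigma"],
            "rho": s["rho"],
            "alpha0": s["alpha0"],
            "beta0": s["beta0"],
            "max_rhat": max(post.rhat.values()),
        }

    comparisons = []
    for roi in sorted({roi for _, roi in combos}):
        avail = sorted(m for m, r_ in combos if r_ == roi)
        for m1, m2 in itertools.combinations(avail, 2):
            pa, pb = posteriors[(m1, roi)], posteriors[(m2, roi)]
            for q in ("r", "tau", "sigma"):
                sa, sb = pa.summaries[q], pb.summaries[q]
                sig = ci_overlap_significant(
                    sa["mean_raw"], (sa["ci_low_raw"], sa["ci_high_raw"]),
                    sb["mean_raw"], (sb["ci_low_raw"], sb["ci_high_raw"]),
                )
                comparisons.append(
                    {
                        "roi": roi,
                        "method_a": m1,
                        "method_b": m2,
                        "quantity": q,
                        "significant": bool(sig),
                    }
                )

    report = _provenance(config, "longitudinal")
    report.update({"per_method": per_method, "comparisons": comparisons, "warnings": []})
    report["_posteriors"] = posteriors
    return report
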