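"""Model/Results interface over the spectral scoring and cohort evaluation.

Two levels mirror the two natural units of analysis:

* :class:`PatientSpectralModel` -- one registered exam.  ``fit()``
  estimates the normal-prostate statistics, conditions the covariance for
  each requested variant and scores the tumor signature, returning a
  :class:`SpectralScores` results object.
* :class:`CohortAggressivenessModel` -- a cohort of per-patient scores
  plus the clinical table.  ``fit()`` runs the linear fits to ISUP grade
  and the resampled logistic ROC evaluation against CsPCa for every
  variant (and, optionally, the clinical covariates), returning a
  :class:`CohortResults` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import conditioning, evaluation, spectral
from .registration import Hypercube, build_hypercube
from .spectral import VARIANTS, NormalStats, TumorSignature


class PatientSpectralModel:
    """Spectral scoring model for one spatially registered exam."""

    def __init__(self, cube: Hypercube, patient_id: str = "patient"):
        self.cube = cube
        self.patient_id = patient_id

    @classmethod
    def from_sequences(
        cls, seqs, prostate_mask, tumor_mask, patient_id: str = "patient", extra_shifts=None
    ) -> "PatientSpectralModel":
        """Register raw channel volumes first, then build the model."""
        cube = build_hypercube(seqs, prostate_mask, tumor_mask, extra_shifts)
        return cls(cube, patient_id)

    def fit(
        self,
        variants=VARIANTS,
        gamma_grid=conditioning.SCORING_GAMMA_GRID,
        evm_removal: float = 0.10,
        evm_trials: int = 6000,
        evm_seed: int | np.random.Generator = 0,
        squared: bool = True,
        z_combine: str = "norm",
    ) -> "SpectralScores":
        stats = spectral.compute_normal_stats(self.cube)
        signature = spectral.primary_signature(self.cube)
        scores: dict[str, float] = {}
        diagnostics: dict[str, dict] = {}
        for variant in variants:
            if variant == "zscore":
                scores[variant] = spectral.z_score(signature, stats, combine=z_combine)
                diagnostics[variant] = {}
                continue
            inv, info = conditioning.conditioned_inverse(
                self.cube.normal_voxels(),
                variant,
                gamma_grid=gamma_grid,
                evm_removal=evm_removal,
                evm_trials=evm_trials,
                evm_seed=evm_seed,
            )
            scores[variant] = spectral.scr(signature, stats, inv, squared=squared)
            diagnostics[variant] = info
        return SpectralScores(
            patient_id=self.patient_id,
            stats=stats,
            signature=signature,
            scores=scores,
            diagnostics=diagnostics,
        )


@dataclass
class SpectralScores:
    """Per-patient scoring results under every covariance variant."""

    patient_id: str
    stats: NormalStats
    signature: TumorSignature
    scores: dict[str, float]
    diagnostics: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "variant": list(self.scores),
                "score": list(self.scores.values()),
            }
        )

    def summary(self) -> str:
        lines = [
            f"Spectral scores -- {self.patient_id}",
            f"  normal voxels: {self.stats.n_voxels}, ROI voxels: {self.signature.n_voxels}",
            f"  contrast (s - mu): {np.round(self.signature.mean - self.stats.mean, 4)}",
            "  variant               score",
        ]
        for v, s in self.scores.items():
            extra = ""
            if "gamma" in self.diagnostics.get(v, {}):
                extra = f"   (gamma={self.diagnostics[v]['gamma']:.2f})"
            lines.append(f"  {v:<20s} {s:>9.4f}{extra}")
        return "\n".join(lines)


class CohortAggressivenessModel:
    """Cohort-level fits of scores (and covariates) to grade and CsPCa."""

    COVARIATES = ("psa_ng_ml", "prostate_vol_cc", "age_years")
    MULTI = (
        ("psa_ng_ml", "prostate_vol_cc", "age_years"),
        ("prostate_vol_cc", "age_years"),
    )

    def __init__(self, scores: pd.DataFrame, cohort: pd.DataFrame):
        """``scores`` is the long frame (patient_id, variant, score)."""
        wide = scores.pivot(index="patient_id", columns="variant", values="score")
        cohort = cohort.set_index("patient_id").loc[wide.index].reset_index()
        self.cohort = cohort
        self.wide = wide.reset_index(drop=True)
        if len(self.wide) != len(self.cohort):
            raise ValueError("scores and cohort table cover different patients")

    @classmethod
    def from_results(cls, results: list[SpectralScores], cohort: pd.DataFrame):
        scores = pd.concat([r.to_frame() for r in results], ignore_index=True)
        return cls(scores, cohort)

    def fit(
        self,
        n_iter: int = 1000,
        train_frac: float = 0.7,
        seed: int = 0,
        include_covariates: bool = True,
        groupings=("scanner", "technique"),
    ) -> "CohortResults":
        results: dict[str, evaluation.EvalResult] = {}
        predictors: dict[str, np.ndarray] = {
            v: self.wide[v].to_numpy() for v in self.wide.columns
        }
        if include_covariates:
            for cov in self.COVARIATES:
                predictors[cov] = self.cohort[cov].to_numpy(dtype=float)
        for name, x in predictors.items():
            results[name] = evaluation.evaluate_variant(
                name, x, self.cohort, n_iter=n_iter, train_frac=train_frac, seed=seed
            )
        multi_auc: dict[str, dict] = {}
        if include_covariates:
            labels = np.array(
                [evaluation.classify_cspca(g) for g in self.cohort["isup"]]
            )
            for combo in self.MULTI:
                X = self.cohort[list(combo)].to_numpy(dtype=float)
                res = evaluation.resampled_auc_ci(
                    X, labels, n_iter=n_iter, train_frac=train_frac, seed=seed
                )
                multi_auc["+".join(combo)] = {
                    "mean_auc": res["mean_auc"],
                    "ci_low": res["ci_low"],
                    "ci_high": res["ci_high"],
                }
        subgroups = {}
        score_vars = {v: self.wide[v].to_numpy() for v in self.wide.columns}
        for grouping in groupings:
            try:
                subgroups[grouping] = evaluation.subgroup_fits(
                    score_vars, self.cohort, grouping
                )
            except ValueError:
                continue
        return CohortResults(
            results=results,
            multi_auc=multi_auc,
            subgroups=subgroups,
            n_patients=len(self.cohort),
            n_iterations=n_iter,
            seed=seed,
        )


@dataclass
class CohortResults:
    """Cohort evaluation: Pearson R vs grade, resampled AUC vs CsPCa."""

    results: dict[str, evaluation.EvalResult]
    multi_auc: dict[str, dict]
    subgroups: dict[str, pd.DataFrame]
    n_patients: int
    n_iterations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.results.items():
            rows.append(
                {
                    "predictor": name,
                    "pearson_r": r.pearson_r,
                    "mean_auc": r.mean_auc,
                    "auc_ci_low": r.auc_ci[0],
                    "auc_ci_high": r.auc_ci[1],
                }
            )
        for name, d in self.multi_auc.items():
            rows.append(
                {
                    "predictor": name,
                    "pearson_r": np.nan,
                    "mean_auc": d["mean_auc"],
                    "auc_ci_low": d["ci_low"],
                    "auc_ci_high": d["ci_high"],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Cohort evaluation -- n={self.n_patients}, "
            f"{self.n_iterations} x 70/30 resampled ROC (seed {self.seed})",
            f"{'predictor':<28s} {'R':>7s} {'AUC':>7s} {'2.5%':>7s} {'97.5%':>7s}",
        ]
        for _, row in df.iterrows():
            r = "" if np.isnan(row.pearson_r) else f"{row.pearson_r:7.3f}"
            lines.append(
                f"{row.predictor:<28s} {r:>7s} {row.mean_auc:7.3f} "
                f"{row.auc_ci_low:7.3f} {row.auc_ci_high:7.3f}"
            )
        for grouping, table in self.subgroups.items():
            lines.append(f"\nSubgroup Pearson R by {grouping}:")
            piv = table[table.variant != "DELTA_R"].pivot(
                index="variant", columns="group", values="r"
            )
            lines.append(piv.round(3).to_string())
            deltas = table[table.variant == "DELTA_R"]
            for _, row in deltas.iterrows():
                lines.append(
                    f"  dR({row['group']}) = {row['r']:+.3f} +/- {row.get('ci95', float('nan')):.3f}"
                )
        return "\n".join(lines)

    def summaries_for_io(self) -> list[dict]:
        return [r.as_dict() for r in self.results.values()] + [
            {"variant": k, **v} for k, v in self.multi_auc.items()
        ]
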