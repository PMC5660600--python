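"""Rate-limiting complex subunit inference by two-stage residual regression.

Stage one removes a protein's own transcript signal:

    P_y = beta1 * T_y + intercept + noise        ->   P_y' = OLS residuals

so P_y' carries only post-transcriptional variability.  Stage two asks
whether the dosage (or transcript) of a complex partner x explains that
residual:

    P_y' = beta2 * X_x + intercept + noise

with an F-test of the predictor against the intercept-only model and BH
FDR across all directed co-membership pairs at that predictor level.  A
significant positive slope nominates x as rate-limiting for y; negative
slopes flag mutually exclusive (paralog-substitution) subunits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr, slope_f_test
from .containers import OmicsMatrix

log = logging.getLogger(__name__)


@dataclass
class ResidualProfile:
    """Stage-one residuals of one protein on its own transcript."""

    residuals: np.ndarray  # aligned to the input samples; NaN where either is missing
    slope: float
    intercept: float
    n_obs: int


def residualize(
    protein_y: np.ndarray, transcript_y: np.ndarray, min_obs: int = 10
) -> ResidualProfile:
    """OLS of protein on transcript (with intercept); returns the residuals.

    Samples missing either value carry NaN residuals.  A constant
    transcript degenerates to an intercept-only fit (centered protein).
    """
    p = np.asarray(protein_y, dtype=float)
    t = np.asarray(transcript_y, dtype=float)
    ok = np.isfinite(p) & np.isfinite(t)
    n = int(ok.sum())
    if n < min_obs:
        raise ValueError(f"need >= {min_obs} complete pairs, got {n}")
    tc = t[ok] - t[ok].mean()
    stt = float(tc @ tc)
    resid = np.full(p.shape, np.nan)
    if stt <= 1e-12:
        log.warning("constant transcript; intercept-only residualisation")
        beta, intercept = 0.0, float(p[ok].mean())
    else:
        beta = float(tc @ p[ok]) / stt
        intercept = float(p[ok].mean() - beta * t[ok].mean())
    resid[ok] = p[ok] - (intercept + beta * t[ok])
    return ResidualProfile(residuals=resid, slope=beta, intercept=intercept, n_obs=n)


def enumerate_directed_pairs(
    complexes: dict[str, set[str]],
    measured_protein: set[str],
    measured_transcript: set[str],
    measured_predictor: set[str],
) -> list[tuple[str, str]]:
    """All directed co-membership pairs (x -> y), deduplicated.

    y must be measured at both protein and transcript level (stage one);
    x must be measured at the predictor level (CNV or transcript).
    """
    if not complexes:
        raise ValueError("empty complex catalog")
    y_ok = measured_protein & measured_transcript
    pairs: set[tuple[str, str]] = set()
    for members in complexes.values():
        for x in members:
            if x not in measured_predictor:
                continue
            for y in members:
                if y != x and y in y_ok:
                    pairs.add((x, y))
    return sorted(pairs)


def test_regulatory_pairs(
    protein: OmicsMatrix,
    mrna: OmicsMatrix,
    cnv: OmicsMatrix | None,
    pairs: list[tuple[str, str]],
    predictor_level: str = "cnv",
    fdr_threshold: float = 0.05,
    min_obs: int = 10,
) -> pd.DataFrame:
    """Stage-two association tests for every directed pair at one level.

    Returns a table (px, py, beta, f_stat, p, fdr, n, sign, significant),
    BH-adjusted jointly across the tested pairs.  Pairs with a
    zero-variance predictor or fewer than ``min_obs`` complete samples are
    skipped (counted in the log).
    """
    if predictor_level not in ("cnv", "transcript"):
        raise ValueError("predictor_level must be 'cnv' or 'transcript'")
    pred = cnv if predictor_level == "cnv" else mrna
    if pred is None:
        raise ValueError(f"no matrix available for predictor level {predictor_level}")

    samples = [s for s in protein.sample_ids if s in set(mrna.sample_ids) & set(pred.sample_ids)]
    P = protein.values[samples]
    T = mrna.values[samples]
    X = pred.values[samples]

    residual_cache: dict[str, np.ndarray | None] = {}

    def residual_of(y: str) -> np.ndarray | None:
        if y not in residual_cache:
            try:
                residual_cache[y] = residualize(
                    P.loc[y].to_numpy(), T.loc[y].to_numpy(), min_obs=min_obs
                ).residuals
            except ValueError:
                residual_cache[y] = None
        return residual_cache[y]

    rows = []
    n_skipped = 0
    for x, y in pairs:
        resid = residual_of(y)
        if resid is None:
            n_skipped += 1
            continue
        try:
            beta, f, p, n = slope_f_test(X.loc[x].to_numpy(), resid)
        except ValueError:
            n_skipped += 1
            continue
        rows.append(
            {"px": x, "py": y, "beta": beta, "f_stat": f, "p": p, "n": n}
        )
    if n_skipped:
        log.info("%d pairs skipped (low n or zero-variance predictor)", n_skipped)
    if not rows:
        raise ValueError("no testable pair")
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    table["sign"] = np.where(table["beta"] >= 0, "positive", "negative")
    table["significant"] = table["fdr"] < fdr_threshold
    table["predictor_level"] = predictor_level
    return table.sort_values(["p", "px", "py"], kind="mergesort").reset_index(drop=True)


def annotate_transcript_support(
    cnv_assoc: pd.DataFrame, transcript_assoc: pd.DataFrame, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Flag CNV-level associations that replicate at transcript level."""
    supported = {
        (r.px, r.py)
        for r in transcript_assoc.itertuples()
        if r.fdr < fdr_threshold
    }
    out = cnv_assoc.copy()
    out["transcript_support"] = [
        (r.px, r.py) in supported for r in cnv_assoc.itertuples()
    ]
    return out


def compare_to_knockdowns(
    assoc: pd.DataFrame, knockdown_effects: pd.DataFrame
) -> tuple[float, float]:
    """Spearman agreement between predicted slopes and knockdown changes.

    ``knockdown_effects`` has columns (px, py, change): the measured
    abundance change of y after depleting x.  Pairs are matched on
    (px, py); requires >= 5 overlapping pairs.  A negative rho is the
    expected signature when positive regulators are depleted.
    """
    merged = assoc.merge(knockdown_effects, on=["px", "py"], how="inner")
    if len(merged) < 5:
        raise ValueError(f"need >= 5 overlapping pairs, got {len(merged)}")
    rho, p = stats.spearmanr(merged["beta"], merged["change"])
    return float(rho), float(p)
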