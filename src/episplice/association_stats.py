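"""ASE-vs-CNE association testing and the signed log-p matrix.

For every (epigenetic feature, AS event type, splice-site bin) cell, the
pooled per-site observations of the alternatively spliced group are
compared with the constitutive (CNE) group by a one-tailed Welch t-test,
with the tail chosen post hoc from the observed mean difference.
Observations from all cell lines are concatenated before testing, so a
direction consistent across cell lines becomes more significant while an
inconsistent one is diluted. p-values are Bonferroni-adjusted over the
full run family (all populated cells by default) and significance is
called at adjusted p < 1e-2 (strict).

Signals can be corrected before testing: ChIP-seq input is subtracted
(negatives preserved — many splice sites have no ChIP signal), and
histone signals can be divided by matched nucleosome occupancy (with a
pseudocount), since only nucleosome-supported histone marks are
meaningful. The association summary is a features x (event type x bin)
matrix of -log10(p) when the feature is higher in the ASE group and
+log10(p) when higher in CNE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .as_annotation import EVENT_TYPES
from .profiling import BIN_IDS

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ALPHA",
    "TestOutcome",
    "CorrectionSpec",
    "one_tailed_t",
    "bonferroni",
    "significance_call",
    "correct_input",
    "correct_nucleosome",
    "apply_correction",
    "run_association_tests",
    "build_matrix",
]

DEFAULT_ALPHA = 1e-2
HIGHER_IN_ASE = "higher_in_ASE"
HIGHER_IN_CNE = "higher_in_CNE"


@dataclass
class TestOutcome:
    direction: str
    p_raw: float
    mean_ase: float
    mean_cne: float
    degenerate: bool = False


@dataclass
class CorrectionSpec:
    """How to correct raw bin/position signals before testing.

    mode ``input_subtract`` subtracts a matched ChIP input level;
    ``nucleosome_divide`` divides by nucleosome occupancy plus
    ``pseudocount`` (> 0, default one read).
    """

    mode: str = "none"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "input_subtract", "nucleosome_divide"):
            raise ValueError(f"unknown correction mode {self.mode!r}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def one_tailed_t(ase_values, cne_values) -> TestOutcome:
    """One-tailed Welch t-test in the direction of the observed means.

    Exactly equal means (including two constant equal samples) give
    p = 0.5 with the tie resolved to ``higher_in_CNE``.
    """
    a = np.asarray(ase_values, dtype=float)
    c = np.asarray(cne_values, dtype=float)
    if len(a) < 2 or len(c) < 2:
        raise ValueError("each group needs >= 2 observations")
    mean_a, mean_c = float(a.mean()), float(c.mean())
    if a.var(ddof=1) == 0 and c.var(ddof=1) == 0 and mean_a == mean_c:
        return TestOutcome(HIGHER_IN_CNE, 0.5, mean_a, mean_c, degenerate=True)
    if mean_a == mean_c:
        return TestOutcome(HIGHER_IN_CNE, 0.5, mean_a, mean_c)
    direction = HIGHER_IN_ASE if mean_a > mean_c else HIGHER_IN_CNE
    alternative = "greater" if mean_a > mean_c else "less"
    res = stats.ttest_ind(a, c, equal_var=False, alternative=alternative)
    return TestOutcome(direction, float(res.pvalue), mean_a, mean_c)


def bonferroni(p_raw: float, m: int) -> float:
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p_raw)


def significance_call(p_adj: float, alpha: float = DEFAULT_ALPHA) -> bool:
    """Strict inequality: adjusted p must be smaller than alpha."""
    return p_adj < alpha


def correct_input(value: float, input_value: float) -> float:
    """Subtract the ChIP-input level; negative results are preserved."""
    return value - input_value


def correct_nucleosome(value: float, nuc_value: float, pseudocount: float = 1.0) -> float:
    """Divide by nucleosome occupancy, stabilised by a pseudocount."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return value / (nuc_value + pseudocount)


def apply_correction(
    obs: pd.DataFrame, reference_obs: pd.DataFrame, spec: CorrectionSpec
) -> pd.DataFrame:
    """Correct a long observation table against a matched reference table.

    ``reference_obs`` holds the input or nucleosome levels collected over
    the same events/bins (its feature column is ignored); matching is by
    (event_id, site_index, bin, cell_line) — or by (event_id, site_index,
    bin) when the reference has a single cell line (a shared track such
    as one nucleosome dataset).
    """
    if spec.mode == "none":
        return obs.copy()
    keys = ["event_id", "site_index", "bin", "cell_line"]
    ref = reference_obs.rename(columns={"value": "ref_value"})
    if ref["cell_line"].nunique() == 1 and obs["cell_line"].nunique() > 1:
        keys = keys[:-1]
        ref = ref.drop(columns=["cell_line"])
    ref = ref[keys + ["ref_value"]].drop_duplicates(subset=keys)
    merged = obs.merge(ref, on=keys, how="left", validate="many_to_one")
    if merged["ref_value"].isna().any():
        raise ValueError("reference track missing for some observations")
    out = merged.drop(columns=["ref_value"]).copy()
    if spec.mode == "input_subtract":
        out["value"] = merged["value"] - merged["ref_value"]
    else:
        out["value"] = merged["value"] / (merged["ref_value"] + spec.pseudocount)
    return out


def run_association_tests(
    obs: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    bonferroni_m: int | None = None,
    event_types: tuple[str, ...] = EVENT_TYPES,
) -> pd.DataFrame:
    """Run every (feature, event type, bin) ASE-vs-CNE test.

    Observations flagged missing are excluded. The Bonferroni family size
    defaults to the number of populated cells in this run and is recorded
    per row. Returns the long results table.
    """
    usable = obs[~obs["missing"]] if "missing" in obs else obs
    cne = usable[usable["event_type"] == "CNE"]
    if cne.empty:
        raise ValueError("no CNE observations: reference group is empty")
    rows = []
    for feature, f_obs in usable.groupby("feature", sort=True):
        f_cne = cne[cne["feature"] == feature]
        for etype in event_types:
            e_obs = f_obs[f_obs["event_type"] == etype]
            for bin_id in BIN_IDS:
                ase_vals = e_obs.loc[e_obs["bin"] == bin_id, "value"].to_numpy()
                cne_vals = f_cne.loc[f_cne["bin"] == bin_id, "value"].to_numpy()
                if len(ase_vals) < 2 or len(cne_vals) < 2:
                    logger.warning(
                        "cell (%s, %s, %s) unpopulated (n=%d/%d); skipped",
                        feature, etype, bin_id, len(ase_vals), len(cne_vals),
                    )
                    continue
                out = one_tailed_t(ase_vals, cne_vals)
                rows.append(
                    {
                        "feature": feature,
                        "event_type": etype,
                        "bin": bin_id,
                        "n_ase": len(ase_vals),
                        "n_cne": len(cne_vals),
                        "mean_ase": out.mean_ase,
                        "mean_cne": out.mean_cne,
                        "direction": out.direction,
                        "p_raw": out.p_raw,
                    }
                )
    res = pd.DataFrame(rows)
    if res.empty:
        raise ValueError("no testable cells")
    m = bonferroni_m if bonferroni_m is not None else len(res)
    logger.info("Bonferroni family size m=%d", m)
    res["bonferroni_m"] = m
    res["p_adj"] = np.minimum(1.0, res["p_raw"] * m)
    res["significant"] = res["p_adj"] < alpha
    return res


def build_matrix(
    results: pd.DataFrame,
    adjusted: bool = True,
    event_types: tuple[str, ...] = EVENT_TYPES,
) -> pd.DataFrame:
    """Features x (event type x bin) matrix of direction-signed log10 p.

    Entries are -log10(p) when the feature is higher in the ASE group,
    +log10(p) when higher in CNE (log10(p) <= 0, so the sign of the entry
    is positive exactly for ASE-elevated cells). Cells absent from
    ``results`` are NaN; ``adjusted=False`` uses raw p-values (the
    variant shown for the correction comparisons).
    """
    pcol = "p_adj" if adjusted else "p_raw"
    if results.duplicated(subset=["feature", "event_type", "bin"]).any():
        raise ValueError("duplicate result cells")
    cols = pd.MultiIndex.from_product(
        [event_types, BIN_IDS], names=["event_type", "bin"]
    )
    features = sorted(results["feature"].unique())
    mat = pd.DataFrame(np.nan, index=features, columns=cols)
    for _, r in results.iterrows():
        if r["event_type"] not in event_types:
            continue
        logp = np.log10(max(r[pcol], np.finfo(float).tiny))
        signed = -logp if r["direction"] == HIGHER_IN_ASE else logp
        mat.loc[r["feature"], (r["event_type"], r["bin"])] = signed
    mat.index.name = "feature"
    return mat
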