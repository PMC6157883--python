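"""The three-step correction pipeline and its diagnostics.

1. Filter: drop every UMI with fewer than T reads (phantom removal).
2. Estimate: fit (E, D) library-wide and per gene from the censored
   reads-per-UMI distribution; fit the shrinkage prior and shrink the
   per-gene loss estimates towards the library-wide loss.
3. Correct: scale each gene's surviving UMI count by 1/(1 - loss_shr).

Because molecules with zero reads are never observable, estimation always
censors at max(T, 1) even when the user filter removes nothing (T <= 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimation, shrinkage
from .branching import FamilySizeDensity
from .readcount import ReadCountModel

__all__ = ["PipelineResult", "FitDiagnostics", "apply_threshold", "run_pipeline",
           "threshold_diagnostics"]

logger = logging.getLogger(__name__)

GENE_COLUMNS = [
    "gene", "n_obs", "efficiency_raw", "depth_raw", "loss_raw", "lambda",
    "efficiency_shr", "depth_shr", "loss_shr", "n_corrected",
    "n_corrected_rounded",
]


@dataclass
class FitDiagnostics:
    """Observed vs predicted reads-per-UMI histogram per candidate threshold.

    ``histogram`` rows: (threshold, k, observed, predicted) with predicted
    counts scaled to the estimated total molecule count (so the bars above
    T should match and bars below T reveal phantom over-abundance).
    ``thresholds`` rows: library-wide (E, D, loss, n_obs, n_total) per
    candidate.
    """

    histogram: pd.DataFrame
    thresholds: pd.DataFrame


@dataclass
class PipelineResult:
    genes: pd.DataFrame
    summary: dict
    diagnostics: FitDiagnostics


def apply_threshold(table: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Remove UMIs with fewer than ``threshold`` reads (T <= 1: no-op)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return table[table["reads"] >= threshold].reset_index(drop=True)


def _fit_library(
    counts: np.ndarray, t_eff: int, table: FamilySizeDensity
) -> tuple[estimation.ParamEstimate, float]:
    sm = estimation.sample_moments(counts, t_eff)
    if sm.n_obs < 2:
        raise ValueError("library-wide fit needs at least 2 surviving UMIs")
    est = estimation.fit_censored(sm.mean, sm.variance, t_eff, table)
    loss = estimation.estimate_loss(est, t_eff, table)
    return est, loss


def run_pipeline(
    table: pd.DataFrame,
    threshold: int,
    density: FamilySizeDensity,
    umis_per_molecule: int = 1,
) -> PipelineResult:
    """Filter, estimate and correct a UMI table (columns gene, umi, reads).

    Returns per-gene results, a library summary and fit diagnostics at the
    chosen threshold.  Genes with fewer than two surviving UMIs, or whose
    moment fit fails, carry no raw estimate and receive the library-wide
    loss (shrinkage coefficient 0).
    """
    filtered = apply_threshold(table, threshold)
    if not len(filtered):
        raise ValueError("no UMIs survive the threshold")
    t_eff = max(int(threshold), 1)

    counts_all = filtered["reads"].to_numpy()
    est_all, loss_all = _fit_library(counts_all, t_eff, density)

    per_gene = filtered.groupby("gene", sort=True)["reads"]
    records = []
    n_failed = 0
    n_boundary = 0
    for gene, counts in per_gene:
        c = counts.to_numpy()
        sm = estimation.sample_moments(c, t_eff)
        rec = {"gene": gene, "n_obs": sm.n_obs, "efficiency_raw": np.nan,
               "depth_raw": np.nan, "loss_raw": np.nan}
        if sm.n_obs >= 2:
            try:
                est = estimation.fit_censored(sm.mean, sm.variance, t_eff, density)
                rec["efficiency_raw"] = est.efficiency
                rec["depth_raw"] = est.depth
                rec["loss_raw"] = estimation.estimate_loss(est, t_eff, density)
                n_boundary += int(est.at_boundary)
            except (ValueError, FloatingPointError) as exc:
                n_failed += 1
                logger.warning("gene %s: raw fit failed (%s)", gene, exc)
        records.append(rec)
    genes = pd.DataFrame(records)

    prior = shrinkage.fit_prior(
        genes["loss_raw"].to_numpy(), genes["n_obs"].to_numpy(), loss_all
    )
    valid = genes["loss_raw"].notna().to_numpy()
    lam = np.where(
        valid, shrinkage.shrinkage_lambda(prior, genes["n_obs"].to_numpy()), 0.0
    )
    genes["lambda"] = lam
    genes["loss_shr"] = shrinkage.shrink(
        np.where(valid, genes["loss_raw"], loss_all), loss_all, lam
    )
    # E and D are shrunk with the same coefficients for reporting only;
    # the count correction uses the shrunken loss exclusively.
    genes["efficiency_shr"] = np.where(
        valid, lam * genes["efficiency_raw"] + (1 - lam) * est_all.efficiency,
        est_all.efficiency,
    )
    genes["depth_shr"] = np.where(
        valid, lam * genes["depth_raw"] + (1 - lam) * est_all.depth,
        est_all.depth,
    )
    genes["n_corrected"] = (
        genes["n_obs"] / (1.0 - genes["loss_shr"]) / umis_per_molecule
    )
    genes["n_corrected_rounded"] = genes["n_corrected"].round().astype(np.int64)
    genes = genes[GENE_COLUMNS]

    n_obs_total = int(len(filtered))
    summary = {
        "threshold": int(threshold),
        "threshold_effective": t_eff,
        "n_obs": n_obs_total,
        "efficiency_all": est_all.efficiency,
        "depth_all": est_all.depth,
        "loss_all": loss_all,
        "n_total": n_obs_total / (1.0 - loss_all) / umis_per_molecule,
        "s": prior.s,
        "u": prior.u,
        "loss_bar": prior.loss_bar,
        "n_genes": int(len(genes)),
        "n_genes_no_raw_fit": int((~valid).sum()),
        "n_gene_fit_failures": n_failed,
        "n_gene_boundary_fits": n_boundary,
    }
    diagnostics = threshold_diagnostics(table, [threshold], density)
    return PipelineResult(genes, summary, diagnostics)


def threshold_diagnostics(
    table: pd.DataFrame,
    candidate_thresholds,
    density: FamilySizeDensity,
) -> FitDiagnostics:
    """Library-wide fits and observed-vs-predicted histograms per candidate T.

    Supports the (visual) threshold choice: pick the lowest T for which the
    observed histogram matches the prediction for k >= T, while bins below
    T show the phantom over-abundance.  Per-candidate fit failures are
    reported as NaN rows, not raised.
    """
    candidates = sorted({int(t) for t in candidate_thresholds})
    if not candidates:
        raise ValueError("candidate_thresholds must be non-empty")
    reads = table["reads"].to_numpy()
    k_max = int(np.quantile(reads, 0.999)) + 1 if reads.size else 1
    hist_rows = []
    thr_rows = []
    for t in candidates:
        surviving = reads[reads >= t]
        t_eff = max(t, 1)
        try:
            est, loss = _fit_library(surviving, t_eff, density)
        except (ValueError, FloatingPointError) as exc:
            logger.warning("threshold %d: library fit failed (%s)", t, exc)
            thr_rows.append(
                {"threshold": t, "n_obs": surviving.size, "efficiency": np.nan,
                 "depth": np.nan, "loss": np.nan, "n_total": np.nan}
            )
            continue
        n_total = surviving.size / (1.0 - loss)
        thr_rows.append(
            {"threshold": t, "n_obs": int(surviving.size),
             "efficiency": est.efficiency, "depth": est.depth, "loss": loss,
             "n_total": n_total}
        )
        ks = np.arange(1, k_max + 1)
        model = ReadCountModel(est.efficiency, est.depth, density)
        pmf_full = model.pmf(np.arange(k_max + 1))
        predicted = n_total * pmf_full[1:]
        # the top bin is an overflow bin: it collects all reads >= k_max,
        # so compare it against the model's tail mass
        predicted[-1] = n_total * max(model.total_mass - pmf_full[:-1].sum(), 0.0)
        observed = np.bincount(
            np.clip(reads, 0, k_max), minlength=k_max + 1
        )[1:]
        for k, obs, pred in zip(ks, observed, predicted):
            hist_rows.append(
                {"threshold": t, "k": int(k), "observed": int(obs),
                 "predicted": float(pred)}
            )
    return FitDiagnostics(pd.DataFrame(hist_rows), pd.DataFrame(thr_rows))
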