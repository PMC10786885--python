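"""Scoring of a dual-condition (vehicle vs. drug) pooled CRISPRi screen.

The pipeline goes from a construct x sample count matrix to classified
hits:

1. depth equalization by hypergeometric downsampling to the shallowest
   sample,
2. exclusion of constructs below a mean-count floor (default 50 reads),
3. per-replicate log2(T10/T0) ratios,
4. phenotype scores: log2 ratios centered on the non-targeting-control
   (NTC) median and divided by the arm's population doublings, then
   standardized by the NTC phenotype spread (z),
5. per-construct negative-binomial Wald tests of T10 vs. T0 with
   Benjamini-Hochberg adjustment,
6. hit classification by significance pattern across the two arms, and an
   essential-gene depletion QC.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ARMS = ("vehicle", "drug")

HIT_CLASSES = (
    "shared_enriched",
    "shared_depleted",
    "drug_selective_enriched",
    "drug_selective_depleted",
    "vehicle_only_enriched",
    "vehicle_only_depleted",
    "not_significant",
)


@dataclass
class NTCStats:
    """Summary of the non-targeting controls used for normalization."""

    median_log2_ratio: float
    sd_phenotype: float
    n_ntc: int


@dataclass
class EssentialQC:
    """Essential-gene depletion benchmark for screen quality control."""

    n_essential_tested: int
    n_depleted: int
    n_enriched: int
    alpha: float
    passed: bool


# ---------------------------------------------------------------------------
# input validation helpers


def validate_library(library: pd.DataFrame) -> None:
    required = {"gene", "protospacer_a", "protospacer_b", "is_ntc"}
    missing = required - set(library.columns)
    if missing:
        raise ValueError(f"library is missing columns: {sorted(missing)}")
    if library.index.duplicated().any():
        dupes = library.index[library.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate construct_ids in library: {dupes}")
    mismatch = library.index[library["is_ntc"].astype(bool) != (library["gene"] == "NTC")]
    if len(mismatch):
        raise ValueError(
            f"is_ntc flag inconsistent with gene=='NTC' for: {mismatch.tolist()[:5]}"
        )


def validate_samples(samples: pd.DataFrame) -> None:
    required = {"arm", "timepoint", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    bad_arm = set(samples["arm"]) - {"baseline", "vehicle", "drug"}
    if bad_arm:
        raise ValueError(f"unknown arm values: {sorted(bad_arm)}")
    bad_tp = set(samples["timepoint"]) - {"T0", "T10"}
    if bad_tp:
        raise ValueError(f"unknown timepoint values: {sorted(bad_tp)}")
    incons = samples[(samples["arm"] == "baseline") != (samples["timepoint"] == "T0")]
    if len(incons):
        raise ValueError(
            f"baseline arm must coincide with timepoint T0; offending samples: "
            f"{incons.index.tolist()}"
        )
    if samples.duplicated(["arm", "timepoint", "replicate"]).any():
        raise ValueError("duplicate arm/timepoint/replicate triples in sample sheet")


def validate_counts(counts: pd.DataFrame, library: pd.DataFrame | None = None) -> None:
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    if library is not None:
        unknown = counts.index.difference(library.index)
        if len(unknown):
            raise ValueError(
                f"counts contain constructs absent from the library: "
                f"{unknown.tolist()[:5]}"
            )


# ---------------------------------------------------------------------------
# counting from reads


def count_protospacers(reads, library: pd.DataFrame, offset: int = 0,
                       length: int = 20):
    """Count exact protospacer matches in a FASTQ stream.

    ``reads`` may be a path (``.gz`` transparently handled) or an open
    text handle.  The substring ``read[offset:offset+length]`` is matched
    exactly against ``protospacer_a`` of each library construct; reads
    matching nothing are tallied as unassigned.

    Returns ``(counts, report)`` with ``counts`` a per-construct integer
    Series and ``report`` containing assigned/total read numbers and the
    match rate (NaN on an empty stream).
    """
    validate_library(library)
    if offset < 0 or length <= 0:
        raise ValueError("offset must be >= 0 and length > 0")
    windows = library["protospacer_a"].str[:length]
    collisions = windows[windows.duplicated(keep=False)]
    if len(collisions):
        raise ValueError(
            "protospacers are not unique over the matching window; collisions: "
            f"{sorted(set(collisions))[:5]}"
        )
    lookup = {seq: cid for cid, seq in windows.items()}

    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        path = str(reads)
        handle = (
            io.TextIOWrapper(gzip.open(path, "rb"))
            if path.endswith(".gz")
            else open(path)
        )
        close = True
    else:
        handle, close = reads, False

    counts = pd.Series(0, index=library.index, dtype=int)
    total = 0
    unassigned = 0
    try:
        for record in SeqIO.parse(handle, "fastq"):
            total += 1
            window = str(record.seq)[offset:offset + length]
            cid = lookup.get(window)
            if cid is None:
                unassigned += 1
            else:
                counts[cid] += 1
    finally:
        if close:
            handle.close()

    if total == 0:
        warnings.warn("empty FASTQ stream: match rate undefined", stacklevel=2)
        rate = float("nan")
    else:
        rate = (total - unassigned) / total
    report = {"total": total, "assigned": total - unassigned,
              "unassigned": unassigned, "match_rate": rate}
    logger.info("counted %d reads, match rate %.4g", total, rate)
    return counts, report


# ---------------------------------------------------------------------------
# normalization


def downsample_to_common_depth(counts: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Subsample every sample column to the minimum column total.

    Reads are drawn without replacement (multivariate hypergeometric), the
    discrete analogue of downsampling sequencing reads to equivalent
    amounts across all samples.
    """
    validate_counts(counts)
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {zero.index.tolist()}")
    target = int(totals.min())
    rng = np.random.default_rng(seed)
    out = {}
    for col in counts.columns:
        vec = counts[col].to_numpy(dtype=np.int64)
        out[col] = rng.multivariate_hypergeometric(vec, target)
    result = pd.DataFrame(out, index=counts.index)
    logger.info("downsampled %d samples to common depth %d", counts.shape[1], target)
    return result


def filter_low_abundance(counts: pd.DataFrame, min_mean: float = 50.0):
    """Drop constructs whose mean count across all samples is below ``min_mean``.

    Returns ``(kept, excluded_ids)``.  Expects depth-equalized counts.
    """
    means = counts.mean(axis=1)
    keep = means >= min_mean
    excluded = counts.index[~keep].tolist()
    if keep.sum() == 0:
        warnings.warn("all constructs excluded by the abundance filter", stacklevel=2)
    logger.info(
        "abundance filter (mean >= %g): kept %d / %d constructs",
        min_mean, int(keep.sum()), len(counts),
    )
    return counts[keep], excluded


def compute_log2_ratios(counts: pd.DataFrame, samples: pd.DataFrame,
                        pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-construct, per-arm, per-replicate log2(T10/T0) ratios.

    A single baseline T0 serves every arm; if several T0 samples exist they
    are matched to T10 replicates by replicate id.  Returns a DataFrame with
    MultiIndex columns ``(arm, replicate)``.
    """
    validate_samples(samples)
    samples = samples.loc[samples.index.intersection(counts.columns)]
    t0 = samples[samples["timepoint"] == "T0"]
    if len(t0) == 0:
        raise ValueError("no T0 baseline sample present")
    per_replicate_t0 = len(t0) > 1
    if per_replicate_t0:
        t0_by_rep = t0.reset_index().set_index("replicate")["sample_id"]

    cols = {}
    for arm in ARMS:
        arm_samples = samples[(samples["arm"] == arm) & (samples["timepoint"] == "T10")]
        if len(arm_samples) == 0:
            raise ValueError(f"no T10 samples for arm {arm!r}")
        for sample_id, meta in arm_samples.iterrows():
            if per_replicate_t0:
                rep = meta["replicate"]
                if rep not in t0_by_rep.index:
                    raise ValueError(f"no T0 sample for replicate {rep!r}")
                t0_col = t0_by_rep[rep]
            else:
                t0_col = t0.index[0]
            num = counts[sample_id].to_numpy(dtype=float) + pseudocount
            den = counts[t0_col].to_numpy(dtype=float) + pseudocount
            cols[(arm, int(meta["replicate"]))] = np.log2(num / den)
    out = pd.DataFrame(cols, index=counts.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["arm", "replicate"])
    return out


def compute_phenotype_scores(ratios: pd.DataFrame, doublings, ntc_flags: pd.Series,
                             min_ntc: int = 10):
    """NTC-centered, doubling-normalized phenotype scores.

    For each arm: ``phenotype = (mean_r L - median_NTC(mean_r L)) / D`` and
    ``z = phenotype / sd_NTC(phenotype)`` where the median and sample SD are
    taken over non-targeting controls.  Returns ``(table, ntc_stats)`` with
    ``table`` carrying MultiIndex columns ``(arm, {log2fc, phenotype, z})``
    and ``ntc_stats`` a per-arm :class:`NTCStats`.
    """
    ntc_flags = ntc_flags.reindex(ratios.index)
    if ntc_flags.isna().any():
        missing = ratios.index[ntc_flags.isna()].tolist()[:5]
        raise ValueError(f"NTC flags missing for constructs: {missing}")
    ntc_mask = ntc_flags.astype(bool).to_numpy()
    n_ntc = int(ntc_mask.sum())
    if n_ntc < min_ntc:
        raise ValueError(
            f"only {n_ntc} NTC constructs survive filtering (need >= {min_ntc}); "
            "NTC normalization would be unreliable"
        )

    out = {}
    ntc_stats = {}
    for arm in ratios.columns.get_level_values("arm").unique():
        if arm not in doublings:
            raise ValueError(f"no doublings value provided for arm {arm!r}")
        d = float(doublings[arm])
        mean_l = ratios[arm].mean(axis=1)
        ntc_median = float(np.median(mean_l.to_numpy()[ntc_mask]))
        phenotype = (mean_l - ntc_median) / d
        sd_ntc = float(np.std(phenotype.to_numpy()[ntc_mask], ddof=1))
        if sd_ntc == 0:
            raise ValueError(f"NTC phenotype SD is zero in arm {arm!r}")
        out[(arm, "log2fc")] = mean_l
        out[(arm, "phenotype")] = phenotype
        out[(arm, "z")] = phenotype / sd_ntc
        ntc_stats[arm] = NTCStats(ntc_median, sd_ntc, n_ntc)
        logger.info(
            "arm %s: NTC median log2 ratio %.4g, NTC phenotype SD %.4g (n=%d)",
            arm, ntc_median, sd_ntc, n_ntc,
        )
    table = pd.DataFrame(out, index=ratios.index)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["arm", "metric"])
    return table, ntc_stats


# ---------------------------------------------------------------------------
# significance testing


def _dispersion_estimates(y_t10: np.ndarray, shrink: float = 0.5) -> np.ndarray:
    """Per-construct NB2 dispersions, shrunk toward a mean-dispersion trend.

    Method-of-moments per construct from the T10 replicates, then a linear
    trend ``alpha(mu) = a + b/mu`` fitted by least squares across constructs,
    and a ``shrink``/(1-``shrink``) blend of trend and raw estimate.
    """
    mu = y_t10.mean(axis=1)
    s2 = y_t10.var(axis=1, ddof=1)
    mu_safe = np.maximum(mu, 1e-8)
    alpha_mom = np.clip((s2 - mu) / mu_safe**2, 1e-8, None)

    design = np.column_stack([np.ones_like(mu_safe), 1.0 / mu_safe])
    coef, *_ = np.linalg.lstsq(design, alpha_mom, rcond=None)
    alpha_trend = np.clip(design @ coef, 1e-8, None)
    return shrink * alpha_trend + (1.0 - shrink) * alpha_mom


def test_significance(counts: pd.DataFrame, samples: pd.DataFrame, arm: str,
                      dispersion_shrink: float = 0.5) -> pd.DataFrame:
    """Negative-binomial Wald test of T10 vs. T0 abundance in one arm.

    Per construct, a log-linear NB2 model (intercept + T10 indicator) is
    fitted with size factors of 1 (counts must already be depth-equalized).
    For this two-group design the MLE of each group mean is its arithmetic
    mean and the Wald statistic has the closed form::

        z = log(mean_T10 / mean_T0) /
            sqrt((1 + a*mu0)/(n0*mu0) + (1 + a*mu1)/(n1*mu1))

    with dispersion ``a`` estimated per construct (method of moments over
    the T10 replicates, shrunk toward a fitted mean-dispersion trend).
    Two-sided p-values use the normal reference; Benjamini-Hochberg
    adjustment is applied across all tested constructs.
    """
    validate_samples(samples)
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    samples = samples.loc[samples.index.intersection(counts.columns)]
    t10_ids = samples[(samples["arm"] == arm) & (samples["timepoint"] == "T10")].index
    t0_ids = samples[samples["timepoint"] == "T0"].index
    if len(t0_ids) == 0:
        raise ValueError("no T0 baseline sample present")
    if len(t10_ids) < 2:
        raise ValueError(
            f"arm {arm!r} has {len(t10_ids)} T10 replicate(s); at least 2 are "
            "required to estimate dispersion"
        )

    y1 = counts[t10_ids].to_numpy(dtype=float)
    y0 = counts[t0_ids].to_numpy(dtype=float)
    n1, n0 = y1.shape[1], y0.shape[1]
    alpha = _dispersion_estimates(y1, shrink=dispersion_shrink)

    mu1 = y1.mean(axis=1)
    mu0 = y0.mean(axis=1)
    # a zero group mean makes the log-link MLE diverge; continuity correction
    mu1 = np.where(mu1 > 0, mu1, 0.5 / n1)
    mu0 = np.where(mu0 > 0, mu0, 0.5 / n0)

    beta1 = np.log(mu1) - np.log(mu0)
    var = (1 + alpha * mu0) / (n0 * mu0) + (1 + alpha * mu1) / (n1 * mu1)
    z = beta1 / np.sqrt(var)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {"wald_z": z, "p": p, "padj": padj, "dispersion": alpha},
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# classification and QC


def classify_hits(pheno_vehicle: pd.DataFrame, pheno_drug: pd.DataFrame,
                  alpha: float = 0.05):
    """Classify constructs by their significance pattern across arms.

    Each input slice needs ``log2fc`` and ``padj`` columns on the same
    construct index.  Significant same-direction in both arms gives a
    ``shared_*`` class; significance in only one arm gives
    ``drug_selective_*`` / ``vehicle_only_*``; anything else (including
    opposite-direction significance) is ``not_significant``.

    Returns ``(classes, listings)`` where ``listings`` maps every non-trivial
    class to the list of construct ids assigned to it.
    """
    if not pheno_vehicle.index.equals(pheno_drug.index):
        diff = pheno_vehicle.index.symmetric_difference(pheno_drug.index)
        raise ValueError(
            f"vehicle and drug tables cover different constructs; symmetric "
            f"difference has {len(diff)} ids, e.g. {diff.tolist()[:5]}"
        )
    sig_v = pheno_vehicle["padj"].to_numpy() < alpha
    sig_d = pheno_drug["padj"].to_numpy() < alpha
    up_v = pheno_vehicle["log2fc"].to_numpy() > 0
    up_d = pheno_drug["log2fc"].to_numpy() > 0

    classes = np.select(
        [
            sig_v & sig_d & up_v & up_d,
            sig_v & sig_d & ~up_v & ~up_d,
            sig_d & ~sig_v & up_d,
            sig_d & ~sig_v & ~up_d,
            sig_v & ~sig_d & up_v,
            sig_v & ~sig_d & ~up_v,
        ],
        [
            "shared_enriched",
            "shared_depleted",
            "drug_selective_enriched",
            "drug_selective_depleted",
            "vehicle_only_enriched",
            "vehicle_only_depleted",
        ],
        default="not_significant",
    )
    result = pd.Series(classes, index=pheno_vehicle.index, name="hit_class")
    listings = {
        cls: result.index[result == cls].tolist()
        for cls in HIT_CLASSES
        if cls != "not_significant"
    }
    logger.info("hit classes: %s", result.value_counts().to_dict())
    return result, listings


def qc_essential_depletion(pheno: pd.DataFrame, essential_genes, alpha: float = 0.05,
                           min_ratio: float = 10.0) -> EssentialQC:
    """Essential-gene depletion benchmark.

    ``pheno`` is one arm's slice with ``gene``, ``log2fc`` and ``padj``
    columns.  The QC passes when significantly depleted essentials outnumber
    significantly enriched ones by more than ``min_ratio``.
    """
    essential_genes = set(essential_genes)
    mask = pheno["gene"].isin(essential_genes)
    if not mask.any():
        raise ValueError("essential gene set does not intersect the library")
    sub = pheno[mask]
    sig = sub["padj"] < alpha
    depleted = int((sig & (sub["log2fc"] < 0)).sum())
    enriched = int((sig & (sub["log2fc"] > 0)).sum())
    passed = depleted > min_ratio * enriched
    logger.info(
        "essential QC: %d tested, %d depleted, %d enriched (alpha=%g) -> %s",
        int(mask.sum()), depleted, enriched, alpha, "pass" if passed else "FAIL",
    )
    return EssentialQC(int(mask.sum()), depleted, enriched, alpha, passed)


# ---------------------------------------------------------------------------
# end-to-end


def score_screen(library: pd.DataFrame, samples: pd.DataFrame, counts: pd.DataFrame,
                 doublings=None, alpha: float = 0.05, min_mean: float = 50.0,
                 pseudocount: float = 1.0, min_ntc: int = 10,
                 seed: int | None = None):
    """Run the full scoring pipeline and return ``(results, meta)``.

    ``results`` has one row per construct surviving the abundance filter
    with per-arm ``log2fc``, ``phenotype``, ``z``, ``p``, ``padj`` columns
    and a ``hit_class``.  ``meta`` records parameters, NTC statistics, the
    excluded constructs and hit-class counts.
    """
    if doublings is None:
        doublings = {"vehicle": 8.0, "drug": 6.0}
    validate_library(library)
    validate_samples(samples)
    validate_counts(counts, library)

    downsampled = downsample_to_common_depth(counts, seed=seed)
    filtered, excluded = filter_low_abundance(downsampled, min_mean=min_mean)
    ratios = compute_log2_ratios(filtered, samples, pseudocount=pseudocount)
    ntc_flags = library["is_ntc"].reindex(filtered.index)
    pheno, ntc_stats = compute_phenotype_scores(
        ratios, doublings, ntc_flags, min_ntc=min_ntc
    )

    tests = {arm: test_significance(filtered, samples, arm) for arm in ARMS}

    results = pd.DataFrame(index=filtered.index)
    results["gene"] = library["gene"].reindex(filtered.index)
    results["is_ntc"] = ntc_flags.astype(bool)
    results["mean_count"] = filtered.mean(axis=1)
    for arm in ARMS:
        results[f"{arm}_log2fc"] = pheno[(arm, "log2fc")]
        results[f"{arm}_phenotype"] = pheno[(arm, "phenotype")]
        results[f"{arm}_z"] = pheno[(arm, "z")]
        results[f"{arm}_p"] = tests[arm]["p"]
        results[f"{arm}_padj"] = tests[arm]["padj"]

    hit_class, listings = classify_hits(
        results[["vehicle_log2fc", "vehicle_padj"]].rename(
            columns={"vehicle_log2fc": "log2fc", "vehicle_padj": "padj"}
        ),
        results[["drug_log2fc", "drug_padj"]].rename(
            columns={"drug_log2fc": "log2fc", "drug_padj": "padj"}
        ),
        alpha=alpha,
    )
    results["hit_class"] = hit_class

    meta = {
        "n_constructs_tested": int(len(results)),
        "n_excluded": int(len(excluded)),
        "excluded": excluded,
        "ntc_stats": {arm: vars(s) for arm, s in ntc_stats.items()},
        "hit_class_counts": results["hit_class"].value_counts().to_dict(),
        "selective_sets": {k: len(v) for k, v in listings.items()},
        "parameters": {
            "doublings": dict(doublings),
            "alpha": alpha,
            "min_mean": min_mean,
            "pseudocount": pseudocount,
            "min_ntc": min_ntc,
            "seed": seed,
        },
    }
    return results, meta
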