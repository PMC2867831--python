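"""Mode-of-ratio normalization: raw window counts to absolute copy number.

The assay compares each element's read count in a sample against the same
element in a reference sample of known ploidy (typically a male blood pool:
diploid autosomes, haploid allosomes). After scaling both samples by their
total unique read counts, the per-element ratio distribution of a largely
diploid genome has a dominant peak; anchoring that peak — the *mode* — to
the reference ploidy converts every ratio into an absolute copy number.
The mean or median of the ratio distribution cannot serve as the anchor:
on an aneuploid genome they sit between peaks and leave every peak at a
non-integer copy number, which is why the mode is used.

Uncertainty is pure Poisson counting: relative errors 1/sqrt(x) (sample)
and 1/sqrt(y) (reference) added in quadrature. Elements whose reference
count is below ``min_ref_reads`` (default 50) carry too little information
and are masked rather than called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .iolib import DepthCNError, GenomeLayout
from .windows import CountTable

DEFAULT_MIN_REF_READS = 50
DEFAULT_BIN_WIDTH = 0.02
DEFAULT_MIN_QUALIFYING = 20


class NormalizationError(DepthCNError):
    """Normalization refused: too few qualifying windows or a degenerate
    ratio distribution."""


@dataclass
class RatioDistribution:
    """Library-size-scaled sample/reference count ratios on qualifying
    (autosomal, well-covered) elements, plus the estimated modal ratio."""

    ratios: np.ndarray          # on qualifying elements only
    element_index: np.ndarray   # indices into the WindowSet
    mode_estimate: float
    bin_width: float
    n_qualifying: int
    sample_total: int
    reference_total: int
    min_ref_reads: int

    def mean(self) -> float:
        return float(np.mean(self.ratios))

    def median(self) -> float:
        return float(np.median(self.ratios))


@dataclass
class CopyNumberProfile:
    """Per-element absolute copy number with 1-sigma bounds and a p-value
    against the expected ploidy; elements with insufficient reference
    coverage are status ``masked`` and carry no call."""

    table: pd.DataFrame
    sample_id: str
    reference_id: str
    mode: float
    ploidy_map: dict[str, float]
    windows: object | None = field(default=None, repr=False, compare=False)

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "called"]

    def __len__(self) -> int:
        return len(self.table)


def _scaled_ratios(sample: CountTable, reference: CountTable) -> np.ndarray:
    x = sample.x.astype(float)
    y = reference.x.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (x / sample.total_unique) / (y / reference.total_unique)


def estimate_mode(
    sample: CountTable,
    reference: CountTable,
    layout: GenomeLayout | None = None,
    min_ref_reads: int = DEFAULT_MIN_REF_READS,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_qualifying: int = DEFAULT_MIN_QUALIFYING,
) -> RatioDistribution:
    """Estimate the modal sample/reference ratio across autosomes.

    Qualifying elements are autosomal with reference count >=
    ``min_ref_reads``. Ratios are histogrammed in fixed bins of
    ``bin_width`` starting at 0; the mode is the mean of the ratios falling
    in the maximal bin and its two neighbours (ties between maximal bins
    broken toward the smaller ratio). Deterministic by construction.
    """
    if sample.windows != reference.windows:
        raise ValueError("sample and reference are counted on different windows")
    if min_ref_reads < 1:
        raise ValueError("min_ref_reads must be >= 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    windows = sample.windows
    qualifying = windows.autosomal_mask() & (reference.x >= min_ref_reads)
    idx = np.flatnonzero(qualifying)
    if idx.size < min_qualifying:
        raise NormalizationError(
            f"only {idx.size} qualifying autosomal elements (reference count >= "
            f"{min_ref_reads}); need at least {min_qualifying}. Use more reads, "
            "larger windows, or a lower min_ref_reads."
        )
    ratios = _scaled_ratios(sample, reference)[idx]
    if not np.any(ratios > 0):
        raise NormalizationError("all qualifying ratios are zero")
    bins = np.floor(ratios / bin_width).astype(np.int64)
    counts = np.bincount(bins)
    top = int(np.argmax(counts))  # argmax takes the first (smallest) max bin
    in_span = (bins >= top - 1) & (bins <= top + 1)
    mode = float(np.mean(ratios[in_span]))
    if mode <= 0:
        raise NormalizationError("modal ratio is zero; cannot anchor copy number")
    return RatioDistribution(
        ratios=ratios,
        element_index=idx,
        mode_estimate=mode,
        bin_width=bin_width,
        n_qualifying=int(idx.size),
        sample_total=sample.total_unique,
        reference_total=reference.total_unique,
        min_ref_reads=min_ref_reads,
    )


def default_ploidy_map(layout: GenomeLayout, sex: str = "male") -> dict[str, float]:
    """Expected reference copy number per chromosome: autosomes 2; for a
    male reference X and Y are 1, for a female X is 2 and Y is 0."""
    if sex not in {"male", "female"}:
        raise ValueError("sex must be 'male' or 'female'")
    ploidy: dict[str, float] = {}
    for c in layout:
        if c.role == "mitochondrial":
            continue
        if c.role == "allosome_X":
            ploidy[c.name] = 1.0 if sex == "male" else 2.0
        elif c.role == "allosome_Y":
            ploidy[c.name] = 1.0 if sex == "male" else 0.0
        else:
            ploidy[c.name] = 2.0
    return ploidy


def normalize_to_reference(
    sample: CountTable,
    reference: CountTable,
    dist: RatioDistribution,
    ploidy_map: Mapping[str, float],
) -> CopyNumberProfile:
    """Convert counts into an absolute copy-number profile.

    For each element with reference count y >= ``min_ref_reads``::

        cn    = ploidy(chrom) * r / mode,   r the library-scaled ratio
        sigma = cn * sqrt(1/x + 1/y)        (x -> 1 in the variance only
                                             when x = 0, so bounds and
                                             p-values stay finite)

    with 1-sigma bounds ``cn -/+ sigma`` (floored at 0) and a two-sided
    normal-tail p-value for the deviation from the expected ploidy.
    Elements below the reference-coverage threshold are masked.
    """
    if sample.windows != reference.windows:
        raise ValueError("sample and reference are counted on different windows")
    if not np.isfinite(dist.mode_estimate) or dist.mode_estimate <= 0:
        raise NormalizationError(f"invalid mode {dist.mode_estimate!r}")
    windows = sample.windows
    missing = sorted(
        {e.chrom for e in windows.elements} - set(ploidy_map.keys())
    )
    if missing:
        raise KeyError(f"ploidy_map lacks chromosomes: {missing}")

    x = sample.x.astype(float)
    y = reference.x.astype(float)
    ploidy = np.array([ploidy_map[e.chrom] for e in windows.elements])
    called = y >= dist.min_ref_reads

    r = np.full(x.shape, np.nan)
    r[called] = (x[called] / dist.sample_total) / (
        y[called] / dist.reference_total
    )
    cn = ploidy * r / dist.mode_estimate

    # Poisson relative errors in quadrature; x=0 uses x->1 in the variance.
    x_eff = np.maximum(x, 1.0)
    cn_eff = ploidy * (x_eff / dist.sample_total) / (
        y / dist.reference_total
    ) / dist.mode_estimate
    sigma = np.full(x.shape, np.nan)
    sigma[called] = cn_eff[called] * np.sqrt(1.0 / x_eff[called] + 1.0 / y[called])

    lower = np.maximum(cn - sigma, 0.0)
    upper = cn + sigma
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(cn - ploidy) / sigma
    # clip into (0, 1]: the normal tail underflows to 0 for extreme z
    p = np.clip(2.0 * sps.norm.sf(z), 1e-300, 1.0)

    table = pd.DataFrame(
        {
            "element_id": [e.element_id for e in windows.elements],
            "chrom": [e.chrom for e in windows.elements],
            "start": windows.starts,
            "end": windows.ends,
            "raw_count": sample.x,
            "ref_count": reference.x,
            "cn": np.where(called, cn, np.nan),
            "sigma": np.where(called, sigma, np.nan),
            "lower": np.where(called, lower, np.nan),
            "upper": np.where(called, upper, np.nan),
            "p_value": np.where(called, p, np.nan),
            "status": np.where(called, "called", "masked"),
        }
    )
    return CopyNumberProfile(
        table=table,
        sample_id=sample.sample_id,
        reference_id=reference.sample_id,
        mode=dist.mode_estimate,
        ploidy_map=dict(ploidy_map),
        windows=windows,
    )


def flag_variant_windows(
    profile: CopyNumberProfile, alpha: float = 0.001, method: str = "raw"
) -> pd.DataFrame:
    """Called elements whose copy number deviates from the expected ploidy
    at ``p < alpha`` (raw threshold, as in genome-wide variant flagging) or,
    with ``method='bh'``, at Benjamini-Hochberg FDR ``alpha``. ``alpha=1``
    returns every called element."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    called = profile.called
    if method == "raw":
        mask = called["p_value"] <= alpha if alpha == 1.0 else called["p_value"] < alpha
    elif method == "bh":
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests(called["p_value"].to_numpy(), alpha, "fdr_bh")
        mask = pd.Series(reject, index=called.index)
    else:
        raise ValueError(f"unknown method {method!r} (raw or bh)")
    return called[mask]


def write_normalization_report(dist: RatioDistribution, path) -> None:
    """Sidecar TSV recording how the normalization was anchored."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"mode\t{dist.mode_estimate:.10g}\n")
        fh.write(f"bin_width\t{dist.bin_width:g}\n")
        fh.write(f"n_qualifying\t{dist.n_qualifying}\n")
        fh.write(f"min_ref_reads\t{dist.min_ref_reads}\n")
        fh.write(f"sample_total\t{dist.sample_total}\n")
        fh.write(f"reference_total\t{dist.reference_total}\n")
        fh.write(f"ratio_mean\t{dist.mean():.10g}\n")
        fh.write(f"ratio_median\t{dist.median():.10g}\n")
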