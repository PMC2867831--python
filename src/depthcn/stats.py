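"""Poisson counting statistics: the error model, the between-sample test,
and the power-based window-size design calculation.

The whole assay rests on one error model: a window's read count x is a
Poisson draw, so its counting uncertainty is sqrt(x) — a window with 100
reads is 100 +/- 10. The model captures sampling noise only, not biological
or protocol variability.

Design calculation: to distinguish copy number a from b (a < b) at
two-sided significance alpha, the diploid-equivalent reads-per-window n
must satisfy

    n * (b - a) / 2  >=  z* sqrt(n a / 2 + n b / 2)
    =>  n >= 2 z*^2 (a + b) / (b - a)^2

with z* the two-sided normal quantile. For (2, 3) at alpha = 0.001 this
gives 108.3, i.e. 110 after rounding up to tens; the matching window size
is genome_size * n / usable_reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps


def poisson_sigma(x):
    """Counting uncertainty sqrt(x) of a read count (elementwise)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


class PoissonErrorModel:
    """The fixed counting error model of the assay."""

    kind = "poisson-counting"

    @staticmethod
    def uncertainty(x):
        return poisson_sigma(x)


@dataclass
class DesignSpec:
    """A window-size design: the copy numbers to distinguish, the
    significance, and the implied reads-per-window and window size."""

    cn_a: float
    cn_b: float
    alpha: float
    reads_per_block: int
    n_usable_reads: int | None = None
    genome_size: int | None = None
    block_size_bp: float | None = None
    block_size_rounded: int | None = None


def reads_per_block(
    cn_a: float, cn_b: float, alpha: float = 0.001, granularity: int = 10
) -> int:
    """Smallest diploid-equivalent reads-per-window separating copy numbers
    ``cn_a`` < ``cn_b`` by at least the two-sided z*(alpha) standard errors
    under Poisson counting, rounded up to ``granularity``."""
    if not (0.0 < cn_a < cn_b):
        raise ValueError(
            f"need 0 < cn_a < cn_b (got {cn_a}, {cn_b}); equal copy numbers "
            "require infinitely many reads"
        )
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if granularity < 1:
        raise ValueError("granularity must be >= 1")
    z = sps.norm.isf(alpha / 2.0)
    n_exact = 2.0 * z * z * (cn_a + cn_b) / (cn_b - cn_a) ** 2
    return int(math.ceil(n_exact / granularity) * granularity)


class BlockSize(NamedTuple):
    raw_bp: float
    rounded_bp: int  # nearest 10 kb


def block_size(n: int, n_usable_reads: int, genome_size: int) -> BlockSize:
    """Window size carrying ``n`` reads on average:
    ``genome_size * n / n_usable_reads``, raw plus a 10 kb-rounded
    convenience value."""
    if n <= 0 or n_usable_reads <= 0 or genome_size <= 0:
        raise ValueError("all design inputs must be positive")
    raw = genome_size * n / n_usable_reads
    return BlockSize(raw, int(round(raw / 10_000.0) * 10_000))


def design(
    cn_a: float = 2.0,
    cn_b: float = 3.0,
    alpha: float = 0.001,
    granularity: int = 10,
    n_usable_reads: int | None = None,
    genome_size: int | None = None,
) -> DesignSpec:
    """Full design calculation; window size filled in when the usable read
    count and genome size are supplied."""
    n = reads_per_block(cn_a, cn_b, alpha, granularity)
    spec = DesignSpec(cn_a, cn_b, alpha, n, n_usable_reads, genome_size)
    if n_usable_reads and genome_size:
        bs = block_size(n, n_usable_reads, genome_size)
        spec.block_size_bp = bs.raw_bp
        spec.block_size_rounded = bs.rounded_bp
    return spec


def compare_samples(profile_a, profile_b) -> pd.DataFrame:
    """Per-element copy-number difference between two profiles normalized
    against the same reference: delta = cn_a - cn_b, sigma in quadrature,
    two-sided normal-tail p-value. Elements masked in either profile are
    masked in the output."""
    ta, tb = profile_a.table, profile_b.table
    same = (
        len(ta) == len(tb)
        and (ta["element_id"].to_numpy() == tb["element_id"].to_numpy()).all()
        and (ta["start"].to_numpy() == tb["start"].to_numpy()).all()
        and (ta["end"].to_numpy() == tb["end"].to_numpy()).all()
    )
    if not same:
        raise ValueError("profiles are defined on different element sets")

    called = (ta["status"].to_numpy() == "called") & (
        tb["status"].to_numpy() == "called"
    )
    cn_a = ta["cn"].to_numpy()
    cn_b = tb["cn"].to_numpy()
    delta = cn_a - cn_b
    sigma = np.hypot(ta["sigma"].to_numpy(), tb["sigma"].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(delta) / sigma
    p = np.clip(2.0 * sps.norm.sf(z), 1e-300, 1.0)

    out = pd.DataFrame(
        {
            "element_id": ta["element_id"],
            "chrom": ta["chrom"],
            "start": ta["start"],
            "end": ta["end"],
            "cn_a": np.where(called, cn_a, np.nan),
            "cn_b": np.where(called, cn_b, np.nan),
            "delta": np.where(called, delta, np.nan),
            "sigma": np.where(called, sigma, np.nan),
            "p_value": np.where(called, p, np.nan),
            "status": np.where(called, "called", "masked"),
        }
    )
    return out
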