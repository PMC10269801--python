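"""Taxon-resolved transcript budgets from metatranscriptome count
tables.

Given long-format read counts per (sample, taxon, function), each
functional category is normalised to the total reads assigned to that
taxon in that sample, so taxa of very different abundance can be
compared on the same footing.  The paired comparison then asks, sample
by sample, whether one taxon devotes a larger share of its
transcriptome to a function (e.g. ribosomal proteins) than another —
the scatter-against-the-1:1-line reading, condensed into an
above-diagonal fraction and a median log2 ratio.

A seeded generator produces synthetic ocean-survey-style tables
(size-fractionated samples, lognormal sequencing depth, multinomial
counts) in which diatoms over-invest in ribosomal proteins and
under-invest in cytoskeleton transcripts relative to other
photosynthetic protists, so the whole pipeline runs without any
external data.  The summary statistics are additions of this package;
the normalisation itself is the standard per-taxon relative abundance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FUNCTIONS",
    "DEFAULT_TAXA",
    "DEFAULT_BASE_PROPORTIONS",
    "TranscriptEffects",
    "taxon_proportions",
    "synthesize_metatranscriptome",
    "normalize",
    "PairedComparison",
    "paired_comparison",
    "expected_log2_ratio",
    "median_log2_interval",
]

logger = logging.getLogger(__name__)

FUNCTIONS = ("ribosomal_protein", "actin", "tubulin", "other")

DEFAULT_TAXA = ("diatom", "other_photosynthetic_protist")

#: Baseline transcriptome shares for a photosynthetic protist:
#: ribosomal proteins a few percent of poly(A)+ reads, actin and
#: tubulin around a percent each, the rest unresolved.
DEFAULT_BASE_PROPORTIONS = {
    "ribosomal_protein": 0.06,
    "actin": 0.012,
    "tubulin": 0.012,
    "other": 0.916,
}

SIZE_FRACTIONS = ("0.8-5um", "5-20um", "20-180um", "180-2000um")


@dataclass(frozen=True)
class TranscriptEffects:
    """Multiplicative diatom-vs-others effects applied by the
    generator: ribosomal-protein share scaled up, actin and tubulin
    shares scaled down; the unresolved remainder absorbs the
    difference."""

    ribosomal_uplift: float = 1.5
    cytoskeleton_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.ribosomal_uplift <= 0 or self.cytoskeleton_factor <= 0:
            raise ValueError("effect multipliers must be positive")


def taxon_proportions(
    taxon: str,
    base: dict | None = None,
    effects: TranscriptEffects | None = None,
) -> dict:
    """Expected functional shares for one taxon.

    Diatoms get the configured uplift/reduction applied to the base
    shares; other taxa use the base shares unchanged.  The ``other``
    category absorbs the adjustment so shares still sum to one.
    """
    base = dict(DEFAULT_BASE_PROPORTIONS if base is None else base)
    effects = effects or TranscriptEffects()
    if set(base) != set(FUNCTIONS):
        raise ValueError(f"base proportions must cover exactly {FUNCTIONS}")
    if any(p < 0 for p in base.values()) or not math.isclose(sum(base.values()), 1.0):
        raise ValueError("base proportions must be non-negative and sum to 1")
    props = dict(base)
    if taxon == "diatom":
        props["ribosomal_protein"] = base["ribosomal_protein"] * effects.ribosomal_uplift
        props["actin"] = base["actin"] * effects.cytoskeleton_factor
        props["tubulin"] = base["tubulin"] * effects.cytoskeleton_factor
        props["other"] = 1.0 - props["ribosomal_protein"] - props["actin"] - props["tubulin"]
    if props["other"] < 0:
        raise ValueError("adjusted proportions exceed 1; reduce the ribosomal uplift")
    return props


def synthesize_metatranscriptome(
    n_samples: int = 66,
    seed: int = 0,
    taxa=DEFAULT_TAXA,
    base_proportions: dict | None = None,
    effects: TranscriptEffects | None = None,
    median_total_reads: float = 2.0e5,
    sigma_log_total: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a synthetic size-fractionated survey count table.

    For every (sample, taxon) the total read count is lognormal
    (median ``median_total_reads``, natural-log sd
    ``sigma_log_total``) and the split across functions is multinomial
    with the taxon's expected shares.  Samples cycle through the four
    standard plankton size fractions.  Fully reproducible per seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    effects = effects or TranscriptEffects()
    records = []
    for i in range(n_samples):
        sample = f"S{i + 1:03d}"
        fraction = SIZE_FRACTIONS[i % len(SIZE_FRACTIONS)]
        for taxon in taxa:
            props = taxon_proportions(taxon, base_proportions, effects)
            total = max(1, int(round(rng.lognormal(np.log(median_total_reads), sigma_log_total))))
            counts = rng.multinomial(total, [props[f] for f in FUNCTIONS])
            for func, count in zip(FUNCTIONS, counts):
                records.append((sample, fraction, taxon, func, int(count)))
    return pd.DataFrame(
        records, columns=["sample", "size_fraction", "taxon", "function", "read_count"]
    )


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon relative abundances.

    Each read count is divided by the total reads of its (sample,
    taxon), so proportions sum to one within every (sample, taxon).
    Pairs with zero total reads are dropped with a logged warning.
    """
    required = {"sample", "taxon", "function", "read_count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if table.duplicated(["sample", "taxon", "function"]).any():
        raise ValueError("(sample, taxon, function) rows must be unique")
    if (table["read_count"] < 0).any():
        raise ValueError("read counts must be non-negative")
    totals = table.groupby(["sample", "taxon"])["read_count"].transform("sum")
    empty = totals == 0
    if empty.any():
        dropped = table.loc[empty, ["sample", "taxon"]].drop_duplicates()
        for sample, taxon in dropped.itertuples(index=False):
            logger.warning("dropping %s/%s: zero total reads", sample, taxon)
    out = table.loc[~empty].copy()
    out["proportion"] = out["read_count"] / totals[~empty]
    return out.drop(columns="read_count")


@dataclass(frozen=True)
class PairedComparison:
    """Per-sample comparison of one function's share between two taxa.

    ``fraction_above`` is the share of common samples where taxon_a's
    proportion strictly exceeds taxon_b's (ties tallied separately);
    the median log2 ratio is computed over samples where both
    proportions are positive, with zero-containing pairs excluded and
    counted in ``n_zero_excluded``.
    """

    function: str
    taxon_a: str
    taxon_b: str
    n_pairs: int
    n_above: int
    n_ties: int
    fraction_above: float
    median_log2_ratio: float
    n_zero_excluded: int
    pairs: pd.DataFrame = field(repr=False, compare=False)


def paired_comparison(
    ra: pd.DataFrame, function: str, taxon_a: str, taxon_b: str
) -> PairedComparison:
    """Compare the relative abundance of ``function`` between two taxa
    across the samples that contain both."""
    sub = ra[ra["function"] == function]
    wide = sub.pivot(index="sample", columns="taxon", values="proportion")
    for taxon in (taxon_a, taxon_b):
        if taxon not in wide.columns:
            wide[taxon] = np.nan
    wide = wide[[taxon_a, taxon_b]].dropna()
    if wide.empty:
        raise ValueError(
            f"no common samples for {taxon_a!r} and {taxon_b!r} ({function!r})"
        )
    a = wide[taxon_a].to_numpy()
    b = wide[taxon_b].to_numpy()
    positive = (a > 0) & (b > 0)
    log2_ratio = np.log2(a[positive] / b[positive])
    return PairedComparison(
        function=function,
        taxon_a=taxon_a,
        taxon_b=taxon_b,
        n_pairs=len(a),
        n_above=int(np.sum(a > b)),
        n_ties=int(np.sum(a == b)),
        fraction_above=float(np.mean(a > b)),
        median_log2_ratio=float(np.median(log2_ratio)) if positive.any() else float("nan"),
        n_zero_excluded=int(len(a) - positive.sum()),
        pairs=wide.reset_index(),
    )


def expected_log2_ratio(
    function: str,
    base: dict | None = None,
    effects: TranscriptEffects | None = None,
    taxon_a: str = "diatom",
    taxon_b: str = "other_photosynthetic_protist",
) -> float:
    """The generator's true log2 ratio of expected shares between two
    taxa for one function."""
    pa = taxon_proportions(taxon_a, base, effects)[function]
    pb = taxon_proportions(taxon_b, base, effects)[function]
    return math.log2(pa / pb)


def median_log2_interval(
    function: str,
    n_samples: int,
    base: dict | None = None,
    effects: TranscriptEffects | None = None,
    median_total_reads: float = 2.0e5,
    sigma_log_total: float = 0.5,
    level: float = 0.95,
    taxon_a: str = "diatom",
    taxon_b: str = "other_photosynthetic_protist",
) -> tuple[float, float]:
    """Analytic sampling interval for the recovered median log2 ratio.

    Delta-method: at depth N a proportion p has sampling variance
    p(1-p)/N, so a per-sample log2 ratio has sd
    (1/ln 2) * sqrt((1-pa)/(pa N) + (1-pb)/(pb N)); the sample median
    of n such values has sd about 1.2533 times the mean's.  Depths are
    lognormal, so the expected reciprocal depth exceeds the reciprocal
    median depth by exp(sigma^2 / 2), which inflates the variance
    accordingly.  The interval is the true ratio plus/minus the normal
    quantile times the resulting sd.
    """
    from scipy.stats import norm

    pa = taxon_proportions(taxon_a, base, effects)[function]
    pb = taxon_proportions(taxon_b, base, effects)[function]
    center = math.log2(pa / pb)
    inv_depth = math.exp(sigma_log_total**2 / 2) / median_total_reads
    per_sample_sd = math.sqrt(
        ((1 - pa) / pa + (1 - pb) / pb) * inv_depth
    ) / math.log(2)
    median_sd = 1.2533 * per_sample_sd / math.sqrt(n_samples)
    z = norm.ppf(0.5 + level / 2)
    return center - z * median_sd, center + z * median_sd
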