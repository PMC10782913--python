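"""Within-sample pair indicators and the exact reversal test.

Each regulator-target pair is encoded per sample as +1 when the regulator's
expression is at least the target's (the tie goes to +1) and -1 otherwise.
Because the indicator only compares two genes within the same sample it is
invariant to any strictly increasing per-sample transform — the property that
lets signatures transfer across platforms without normalization.

A pair is "reversed" between two phenotype groups (LGG vs GBM) when its
dominant ordering flips; this is tested with Fisher's exact test on the
2x2 table of (+1/-1) x (group). All probability arithmetic is done in
log10 space via log-gamma: the selection cutoff of p < 1e-70 sits far below
anything representable through naive factorial ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .expression_io import ClinicalTable, ExpressionMatrix, ValidationError
from .regulator_pairing import PairCatalog

LOG10 = np.log(10.0)
#: relative slack on log-probabilities when deciding "as or more extreme",
#: guarding against float ties between tables of equal exact probability
TWO_SIDED_REL_TOL = 1e-7
#: log10 selection cutoff for reversed pairs (p < 1e-70)
DEFAULT_LOG10_THRESHOLD = -70.0


@dataclass
class PairIndicatorMatrix:
    """Pairs x samples matrix with entries in {+1, -1}."""

    pairs: list[tuple[str, str]]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValidationError("indicator shape does not match pair/sample lists")
        if not np.isin(self.values, (-1, 1)).all():
            raise ValidationError("indicator entries must be exactly +1 or -1")
        self.values = self.values.astype(np.int8)
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("duplicate pairs in indicator matrix")

    def row(self, pair: tuple[str, str]) -> np.ndarray:
        try:
            return self.values[self.pairs.index(tuple(pair))]
        except ValueError:
            raise KeyError(f"pair {pair} not in indicator matrix") from None

    def subset_pairs(self, pairs: Sequence[tuple[str, str]]) -> "PairIndicatorMatrix":
        rows = [self.pairs.index(tuple(p)) for p in pairs]
        return PairIndicatorMatrix(
            [tuple(p) for p in pairs], list(self.sample_ids), self.values[rows]
        )

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{m}|{g}" for m, g in self.pairs]
        return pd.DataFrame(self.values, index=idx, columns=self.sample_ids)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "pair"
        df.to_csv(path, sep="\t")


@dataclass
class ReversalTestResult:
    pair: tuple[str, str]
    a: int
    b: int
    c: int
    d: int
    log10_p_point: float
    log10_p_two_sided: float
    selected: bool


def encode_pairs(expr: ExpressionMatrix, catalog: PairCatalog) -> PairIndicatorMatrix:
    """Encode every catalog pair as a +1/-1 within-sample ordering indicator."""
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = np.empty((len(catalog), expr.n_samples), dtype=np.int8)
    for k, gp in enumerate(catalog.pairs):
        for gene in (gp.regulator, gp.target):
            if gene not in gene_index:
                raise KeyError(
                    f"gene {gene!r} of pair {gp.regulator}|{gp.target} "
                    "missing from expression matrix"
                )
        m = expr.values[gene_index[gp.regulator]]
        g = expr.values[gene_index[gp.target]]
        rows[k] = np.where(m >= g, 1, -1)
    return PairIndicatorMatrix(catalog.pair_keys(), list(expr.sample_ids), rows)


def contingency_counts(
    indicators: PairIndicatorMatrix,
    clinical: ClinicalTable,
    group1: str,
    group2: str,
) -> pd.DataFrame:
    """Per-pair 2x2 counts: a/b = group1 samples at +1/-1, c/d = group2."""
    grade = clinical.data.set_index("sample_id")["grade"]
    missing = [s for s in indicators.sample_ids if s not in grade.index]
    if missing:
        raise ValidationError(f"samples without clinical annotation: {missing[:5]}")
    labels = grade.loc[indicators.sample_ids].to_numpy()
    unlabeled = [
        s for s, lab in zip(indicators.sample_ids, labels)
        if lab not in (group1, group2)
    ]
    if unlabeled:
        raise ValidationError(
            f"samples labeled neither {group1!r} nor {group2!r}: {unlabeled[:5]}"
        )
    g1 = labels == group1
    g2 = labels == group2
    pos = indicators.values == 1
    a = (pos & g1).sum(axis=1)
    b = (~pos & g1).sum(axis=1)
    c = (pos & g2).sum(axis=1)
    d = (~pos & g2).sum(axis=1)
    return pd.DataFrame(
        {"regulator": [p[0] for p in indicators.pairs],
         "target": [p[1] for p in indicators.pairs],
         "a": a, "b": b, "c": c, "d": d}
    )


def _check_counts(a: int, b: int, c: int, d: int) -> tuple[int, int, int, int]:
    counts = (int(a), int(b), int(c), int(d))
    if any(x < 0 for x in counts):
        raise ValidationError(f"negative count in table {counts}")
    if sum(counts) == 0:
        raise ValidationError("all counts are zero")
    return counts


def _log10_point(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = a + b + c + d
    num = (gammaln(a + b + 1) + gammaln(c + d + 1)
           + gammaln(a + c + 1) + gammaln(b + d + 1))
    den = (gammaln(a + 1) + gammaln(b + 1) + gammaln(c + 1)
           + gammaln(d + 1) + gammaln(n + 1))
    return (num - den) / LOG10


def fisher_point_log10(a: int, b: int, c: int, d: int) -> float:
    """log10 hypergeometric point probability of one 2x2 table.

    Computed through log-gamma so tables with hundreds of samples per margin
    do not underflow.
    """
    a, b, c, d = _check_counts(a, b, c, d)
    return float(_log10_point(np.array(a), np.array(b), np.array(c), np.array(d)))


def fisher_two_sided_log10(a: int, b: int, c: int, d: int) -> float:
    """log10 two-sided Fisher exact p for one 2x2 table.

    Sums, over all tables with the observed margins, the point probabilities
    that are <= the observed one (with a small relative slack on the log
    scale against float ties); the sum is accumulated with logsumexp.
    """
    a, b, c, d = _check_counts(a, b, c, d)
    row1, col1 = a + b, a + c
    n = a + b + c + d
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    a_all = np.arange(lo, hi + 1)
    log10_all = _log10_point(a_all, row1 - a_all, col1 - a_all, (n - row1) - (col1 - a_all))
    log10_obs = log10_all[a - lo]
    cut = log10_obs + TWO_SIDED_REL_TOL * abs(log10_obs)
    included = log10_all[log10_all <= cut]
    total = logsumexp(included * LOG10) / LOG10
    return float(min(total, 0.0))


def reversal_test(
    indicators: PairIndicatorMatrix,
    clinical: ClinicalTable,
    group1: str = "LGG",
    group2: str = "GBM",
    log10_threshold: float = DEFAULT_LOG10_THRESHOLD,
) -> list[ReversalTestResult]:
    """Fisher reversal test for every pair between two phenotype groups."""
    counts = contingency_counts(indicators, clinical, group1, group2)
    results = []
    for pair, row in zip(indicators.pairs, counts.itertuples(index=False)):
        point = fisher_point_log10(row.a, row.b, row.c, row.d)
        two = fisher_two_sided_log10(row.a, row.b, row.c, row.d)
        results.append(
            ReversalTestResult(
                pair=pair, a=int(row.a), b=int(row.b), c=int(row.c), d=int(row.d),
                log10_p_point=point, log10_p_two_sided=two,
                selected=two < log10_threshold,
            )
        )
    return results


def select_reversed_pairs(
    results: list[ReversalTestResult],
    log10_threshold: float = DEFAULT_LOG10_THRESHOLD,
) -> list[ReversalTestResult]:
    """Pairs whose two-sided log10 p falls below the cutoff, most extreme first."""
    kept = [r for r in results if r.log10_p_two_sided < log10_threshold]
    return sorted(kept, key=lambda r: r.log10_p_two_sided)


def results_to_frame(results: list[ReversalTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair": [f"{r.pair[0]}|{r.pair[1]}" for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "d": [r.d for r in results],
            "log10_p_point": [r.log10_p_point for r in results],
            "log10_p_two_sided": [r.log10_p_two_sided for r in results],
            "selected": [r.selected for r in results],
        }
    )


def reversal_proportion(
    indicators: PairIndicatorMatrix,
    clinical: ClinicalTable,
    groups: Sequence[str],
) -> pd.DataFrame:
    """Per-pair fraction of samples with indicator +1, one column per group.

    Across (normal, LGG, GBM) a monotone trend in these proportions tracks
    progressive loss of the normal ordering during glioma progression.
    """
    grade = clinical.data.set_index("sample_id")["grade"]
    labels = grade.reindex(indicators.sample_ids).to_numpy()
    out = {}
    for g in groups:
        mask = labels == g
        if not mask.any():
            raise ValidationError(f"group {g!r} has no samples")
        out[g] = (indicators.values[:, mask] == 1).mean(axis=1)
    idx = [f"{m}|{g}" for m, g in indicators.pairs]
    return pd.DataFrame(out, index=idx)
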