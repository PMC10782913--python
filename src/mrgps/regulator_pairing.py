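"""m6A regulator curation and correlation-based regulator-target pairing.

A regulator-target gene pair is formed whenever the Pearson correlation
between an m6A regulator (writer, eraser or reader) and a non-regulator gene
passes |r| > r_min at two-sided p < p_max; the p-value comes from the exact
t-transformation t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix, ValidationError

REGULATOR_CLASSES = ("writer", "eraser", "reader")


class PairingError(ValueError):
    """Raised for undefined correlations or impossible pairing requests."""


@dataclass
class RegulatorSet:
    """Curated m6A regulators, each a (symbol, class) entry."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        symbols = [s for s, _ in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValidationError("duplicate regulator symbols")
        bad = {c for _, c in self.entries} - set(REGULATOR_CLASSES)
        if bad:
            raise ValidationError(
                f"unknown regulator class(es) {sorted(bad)}; expected one of "
                f"{REGULATOR_CLASSES}"
            )

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in {s.upper() for s in self.symbols}


class GenePair(NamedTuple):
    regulator: str
    target: str
    r: float
    p: float


@dataclass
class PairCatalog:
    """Regulator-target pairs passing the correlation thresholds."""

    pairs: list[GenePair]
    r_min: float
    p_max: float

    def __post_init__(self) -> None:
        for gp in self.pairs:
            if not (abs(gp.r) > self.r_min and gp.p < self.p_max):
                raise ValidationError(
                    f"pair {gp.regulator}|{gp.target} violates thresholds "
                    f"(r={gp.r}, p={gp.p})"
                )

    @property
    def target_genes(self) -> list[str]:
        """Unique targets, in first-appearance order."""
        return list(dict.fromkeys(gp.target for gp in self.pairs))

    def pair_keys(self) -> list[tuple[str, str]]:
        return [(gp.regulator, gp.target) for gp in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["regulator", "target", "r", "p"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.pairs)


def load_regulators(extra_path: str | Path | None = None) -> RegulatorSet:
    """Load the packaged default m6A regulator list, optionally extended.

    The default ships 8 writers, 2 erasers and 15 readers. ``extra_path``
    points to a TSV with columns ``symbol`` and ``class`` whose rows are
    appended; symbols already present (case-insensitively) are dropped.
    """
    ref = resources.files("mrgps.data").joinpath("regulators.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    entries = [(str(s).upper(), str(c)) for s, c in zip(df["symbol"], df["class"])]
    if extra_path is not None:
        extra = pd.read_csv(extra_path, sep="\t")
        known = {s for s, _ in entries}
        for s, c in zip(extra["symbol"], extra["class"]):
            c = str(c).strip().lower()
            if c not in REGULATOR_CLASSES:
                raise ValidationError(
                    f"unknown regulator class {c!r} for {s!r}; "
                    f"expected one of {REGULATOR_CLASSES}"
                )
            s = str(s).upper()
            if s not in known:
                entries.append((s, c))
                known.add(s)
    return RegulatorSet(entries)


def pearson(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Pearson r with its two-sided p from the t-distribution on n-2 df."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise PairingError("vectors must have equal length")
    if x.size < 3:
        raise PairingError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PairingError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _corr_with_p(reg_values: np.ndarray, tgt_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise correlations of every regulator row against every target row."""
    n = reg_values.shape[1]
    rc = reg_values - reg_values.mean(axis=1, keepdims=True)
    tc = tgt_values - tgt_values.mean(axis=1, keepdims=True)
    rs = np.sqrt((rc**2).sum(axis=1))
    ts = np.sqrt((tc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc @ tc.T) / np.outer(rs, ts)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def build_pair_catalog(
    expr: ExpressionMatrix,
    regs: RegulatorSet,
    r_min: float = 0.5,
    p_max: float = 0.01,
) -> PairCatalog:
    """Test every regulator x non-regulator combination in ``expr``.

    Pairs with |r| > r_min and p < p_max are kept (strict inequalities).
    Symbols are matched case-insensitively via upper-casing.
    """
    reg_syms = {s.upper() for s in regs.symbols}
    upper = [g.upper() for g in expr.gene_ids]
    reg_idx = [i for i, g in enumerate(upper) if g in reg_syms]
    tgt_idx = [i for i, g in enumerate(upper) if g not in reg_syms]
    if not reg_idx:
        raise PairingError("no regulator symbols present in the expression matrix")
    if not tgt_idx:
        raise PairingError("no non-regulator genes present in the expression matrix")
    if expr.n_samples < 3:
        raise PairingError("need at least 3 samples to correlate")

    r, p = _corr_with_p(expr.values[reg_idx], expr.values[tgt_idx])
    keep = (np.abs(r) > r_min) & (p < p_max) & np.isfinite(r)
    pairs = [
        GenePair(expr.gene_ids[reg_idx[i]], expr.gene_ids[tgt_idx[j]],
                 float(r[i, j]), float(p[i, j]))
        for i, j in zip(*np.nonzero(keep))
    ]
    return PairCatalog(pairs, r_min=r_min, p_max=p_max)


def hypergeometric_overlap(
    catalog_pairs: set,
    verified_pairs: set,
    universe_pairs: set,
) -> float:
    """log10 upper-tail hypergeometric probability of the observed overlap.

    Models drawing ``len(catalog_pairs)`` pairs without replacement from the
    universe, of which ``len(verified_pairs)`` are marked (e.g. CLIP-verified),
    and asks for P(overlap >= observed).
    """
    if not universe_pairs:
        raise PairingError("universe of pairs is empty")
    if not catalog_pairs <= universe_pairs or not verified_pairs <= universe_pairs:
        raise PairingError("catalog and verified sets must be subsets of the universe")
    M = len(universe_pairs)
    K = len(verified_pairs)
    N = len(catalog_pairs)
    k = len(catalog_pairs & verified_pairs)
    if k == 0:
        return 0.0
    # P(X >= k) = sf(k - 1)
    return float(stats.hypergeom.logsf(k - 1, M, K, N) / np.log(10.0))
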