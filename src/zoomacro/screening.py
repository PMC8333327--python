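"""Distribution screening: transform selection, correlation screens and the
collinearity filter defining the modelling covariate sets.

Variables are offered four candidate transforms (square root, natural log,
log10, cube root); the one whose transformed sample scores the highest
Shapiro-Wilk p-value wins.  Natural log and log10 always tie (affinely
related, and W is affine-invariant); the tie resolves by the fixed priority
sqrt < ln < log10 < cbrt -- first listed wins.

Pairs of covariates with |Spearman rho| >= 0.7 are resolved by dropping the
member whose best transform is further from normality (more missing values
breaks near-ties).  The temperature-oxygen pair is never mutually resolved:
two parallel covariate sets are emitted, one containing temperature and one
oxygen, so both can be assessed as drivers despite their anticollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

COLLINEARITY_THRESHOLD = 0.7
TRANSFORMS = ("sqrt", "ln", "log10", "cbrt")     # priority order for ties


@dataclass
class NormalityResult:
    W: float
    p: float


@dataclass
class TransformChoice:
    transform: str
    results: dict[str, NormalityResult] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    stars: str


def shapiro_wilk(x) -> NormalityResult:
    """Shapiro-Wilk normality test (W is affine-invariant)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 finite values")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = stats.shapiro(x)
    return NormalityResult(W=float(w), p=float(p))


def apply_transform(x, transform: str):
    """Element-wise sqrt, ln, log10 or cube root."""
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    if transform == "sqrt":
        if np.any(x[ok] < 0):
            raise ValueError("sqrt transform needs non-negative values")
        return np.sqrt(x)
    if transform in ("ln", "log10"):
        if np.any(x[ok] <= 0):
            bad = np.nonzero(ok & (x <= 0))[0]
            raise ValueError(f"log transform needs positive values "
                             f"(offending indices {bad[:5].tolist()})")
        return np.log(x) if transform == "ln" else np.log10(x)
    if transform == "cbrt":
        return np.cbrt(x)
    raise ValueError(f"unknown transform {transform!r}")


def select_transform(x, candidates: tuple[str, ...] = TRANSFORMS,
                     ) -> TransformChoice:
    """Pick the candidate transform whose result is closest to normal.

    Inapplicable candidates (domain violations) are skipped; ties on the
    Shapiro-Wilk p resolve to the first-listed candidate.
    """
    results: dict[str, NormalityResult] = {}
    for t in candidates:
        try:
            results[t] = shapiro_wilk(apply_transform(x, t))
        except ValueError:
            continue
    if not results:
        raise ValueError("no candidate transform applicable to this sample")
    # ln and log10 tie analytically (affine-related); compare p values with
    # a tolerance so floating-point jitter cannot override the priority rule
    p_best = max(r.p for r in results.values())
    tied = [t for t in candidates
            if t in results and results[t].p >= p_best - 1e-9]
    return TransformChoice(transform=tied[0], results=results)


def stars(p: float) -> str:
    """Significance label: *** / ** / * / ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with pairwise-complete handling."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return CorrelationResult(rho=np.nan, p=np.nan, n=n, stars="ns")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return CorrelationResult(rho=float(rho), p=float(p), n=n, stars=stars(float(p)))


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Long-form pairwise Spearman matrix (var1, var2, rho, p, stars, n)."""
    cols = list(table.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            r = spearman(table[a], table[b])
            rows.append((a, b, r.rho, r.p, r.stars, r.n))
            if a != b:
                rows.append((b, a, r.rho, r.p, r.stars, r.n))
    return pd.DataFrame(rows, columns=["var1", "var2", "rho", "p", "stars", "n"])


def _rho_square(table: pd.DataFrame) -> pd.DataFrame:
    long = spearman_matrix(table)
    return long.pivot(index="var1", columns="var2", values="rho").loc[
        table.columns, table.columns]


@dataclass
class CovariateSets:
    temperature_set: list[str]
    oxygen_set: list[str]
    dropped: list[tuple[str, str, float]]     # (dropped, kept, rho)

    def to_dict(self) -> dict:
        return {"temperature_set": self.temperature_set,
                "oxygen_set": self.oxygen_set,
                "dropped": [{"dropped": d, "kept": k, "rho": r}
                            for d, k, r in self.dropped]}


def collinearity_filter(table: pd.DataFrame,
                        threshold: float = COLLINEARITY_THRESHOLD,
                        forced_pair: tuple[str, str] = ("temperature", "oxygen"),
                        ) -> CovariateSets:
    """Resolve |rho| >= threshold covariate pairs; emit two parallel sets.

    Offending pairs are resolved largest |rho| first by dropping the member
    whose best-transform Shapiro-Wilk p is lower (near-equal normality,
    Delta p < 1e-6, breaks on the count of missing values).  The forced
    temperature/oxygen pair is never resolved against itself; instead the
    surviving covariates are emitted twice, once with temperature and once
    with oxygen.
    """
    cols = [c for c in table.columns]
    normality: dict[str, float] = {}
    n_missing: dict[str, int] = {}
    for c in cols:
        x = table[c].to_numpy(float)
        n_missing[c] = int((~np.isfinite(x)).sum())
        try:
            choice = select_transform(x)
            normality[c] = max(r.p for r in choice.results.values())
        except ValueError:
            normality[c] = -1.0

    active = list(cols)
    dropped_log: list[tuple[str, str, float]] = []
    forced = frozenset(forced_pair)
    while True:
        rho = _rho_square(table[active]).abs()
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                if frozenset((a, b)) == forced:
                    continue
                r = float(rho.loc[a, b])
                if np.isfinite(r) and r >= threshold:
                    if best is None or r > best[0]:
                        best = (r, a, b)
        if best is None:
            break
        r, a, b = best
        if a in forced or b in forced:
            # the forced members anchor the parallel model variants and are
            # never sacrificed to an incidental conflict
            drop = b if a in forced else a
        else:
            pa, pb = normality[a], normality[b]
            if abs(pa - pb) < 1e-6:
                drop = a if n_missing[a] > n_missing[b] else b
            else:
                drop = a if pa < pb else b
        keep = b if drop == a else a
        active.remove(drop)
        dropped_log.append((drop, keep, r))

    t_name, o_name = forced_pair
    temp_set = [c for c in active if c != o_name]
    oxy_set = [c for c in active if c != t_name]
    return CovariateSets(temperature_set=temp_set, oxygen_set=oxy_set,
                         dropped=dropped_log)
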