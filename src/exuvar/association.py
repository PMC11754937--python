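"""Mantel permutation tests between distance matrices.

The Mantel statistic r is the Pearson correlation over the n(n-1)/2
off-diagonal upper-triangle entries of two distance matrices on the same
accessions. Its null distribution is built by simultaneously permuting the
rows and columns of one matrix, which respects the dependence structure of
pairwise distances. The screen runs every chemical x driver pair and
applies a Bonferroni correction over the whole family of tests it ran.

The alternative is one-sided (positive association) by default; p-values
use the add-one estimator p = (1 + #{r_perm >= r_obs}) / (1 + n_perm), so
they can never be exactly zero. For very small matrices the permutation
null can be enumerated exhaustively.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = ["MantelResult", "mantel_r", "mantel_test", "mantel_screen"]


@dataclasses.dataclass
class MantelResult:
    label_a: str
    label_b: str
    r: float
    p: float
    p_adj: float
    n_perm: int
    n: int
    alternative: str = "greater"


def _check_pair(a: DistanceMatrix, b: DistanceMatrix) -> None:
    if a.labels != b.labels:
        raise ValueError("distance matrices have mismatched labels/order")
    if a.n < 4:
        raise ValueError("Mantel test needs n >= 4 accessions")


def _triangle(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel_r(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Pearson correlation of the two upper triangles."""
    _check_pair(a, b)
    x, y = _triangle(a.d), _triangle(b.d)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a distance triangle")
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = 0,
    alternative: str = "greater",
    method: str = "monte_carlo",
) -> MantelResult:
    """Permutation Mantel test.

    ``method='monte_carlo'`` samples ``n_perm`` simultaneous row/column
    permutations of B; ``method='exhaustive'`` enumerates all n!
    permutations (n <= 8) and reports the exact permutation p-value
    p = #{r_perm >= r_obs} / n! (the identity permutation is included in
    the enumeration).
    """
    _check_pair(a, b)
    r_obs = mantel_r(a, b)
    x = _triangle(a.d)
    xc = x - x.mean()
    xnorm = np.sqrt((xc**2).sum())

    def r_of(perm: np.ndarray) -> float:
        bp = b.d[np.ix_(perm, perm)]
        y = _triangle(bp)
        yc = y - y.mean()
        denom = xnorm * np.sqrt((yc**2).sum())
        return float((xc * yc).sum() / denom)

    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")

    def exceeds(r_p: float) -> bool:
        if alternative == "greater":
            return r_p >= r_obs - 1e-12
        return abs(r_p) >= abs(r_obs) - 1e-12

    n = a.n
    if method == "exhaustive":
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        total = math.factorial(n)
        count = sum(
            exceeds(r_of(np.array(p))) for p in itertools.permutations(range(n))
        )
        return MantelResult(
            a.kind, b.kind, r_obs, count / total, count / total, total, n,
            alternative,
        )
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} < 99: p-value resolution is coarse")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if exceeds(r_of(perm)):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(a.kind, b.kind, r_obs, p, p, n_perm, n, alternative)


def mantel_screen(
    chem: dict[str, DistanceMatrix],
    drivers: dict[str, DistanceMatrix],
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> pd.DataFrame:
    """All chemical x driver Mantel tests with one Bonferroni family.

    The family size is the number of tests actually executed in this
    invocation; p_adj = min(1, p * family size). Returns a DataFrame
    sorted by adjusted p.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cname, cmat in chem.items():
        for dname, dmat in drivers.items():
            res = mantel_test(
                cmat, dmat.reorder(cmat.labels), n_perm=n_perm, seed=rng,
                alternative=alternative,
            )
            rows.append(
                dict(
                    matrix_a=cname, matrix_b=dname, n=res.n, r=res.r, p=res.p,
                    n_perm=res.n_perm,
                )
            )
    df = pd.DataFrame(
        rows, columns=["matrix_a", "matrix_b", "n", "r", "p", "n_perm"]
    )
    family = len(df)
    df["p_adj"] = np.minimum(1.0, df["p"] * family) if family else df.get("p", [])
    df["family_size"] = family
    return df.sort_values("p_adj", kind="stable").reset_index(drop=True) if family else df
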