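"""Inferential layer: biclique subgraph detection and circuit comparisons.

The central question is whether any *group* of circuits — an input-region
subset crossed with an output-region subset (a biclique in the bipartite
connectivity graph) — is stronger than chance. :class:`SubgraphScan` scores
every candidate biclique by its cluster mass, the sum over member circuits of
the one-sample standardized mean minus a cluster-forming threshold, and
calibrates the best score against a permutation null in which cell-to-circuit
assignments are shuffled (within subtype and metric, preserving per-circuit
n). Family-wise error over the whole candidate family is controlled by
comparing the observed best score with the permutation distribution of the
*maximum* score across all candidates (max-statistic FWE control).

Also here: Cohen's d effect sizes, per-circuit Wilcoxon rank-sum subtype
comparisons on the binary-response metric, and the Kruskal-Wallis omnibus
test across circuits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegenerateStatisticError
from .matrix import StrengthMatrix
from .regions import CircuitSpec

DEFAULT_CLUSTER_THRESHOLD = 2.0


def circuit_statistic(values: np.ndarray) -> float:
    """One-sample standardized mean: mean / (sd / sqrt(n))."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateStatisticError("circuit statistic requires n >= 2")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateStatisticError("zero variance: circuit statistic undefined")
    return float(values.mean() / (sd / np.sqrt(values.size)))


def cohens_d(values: np.ndarray, reference: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation over both samples."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateStatisticError("Cohen's d requires n >= 2 in both samples")
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        raise DegenerateStatisticError("zero pooled SD: Cohen's d undefined")
    return float((x.mean() - y.mean()) / pooled)


@dataclass(frozen=True)
class SubgraphHypothesis:
    """A candidate biclique: input subset x output subset."""

    input_set: tuple[str, ...]
    output_set: tuple[str, ...]

    @property
    def member_circuits(self) -> tuple[CircuitSpec, ...]:
        return tuple(CircuitSpec(i, o) for i in self.input_set for o in self.output_set)

    @property
    def label(self) -> str:
        return "{%s} x {%s}" % (", ".join(self.input_set), ", ".join(self.output_set))


def subgraph_score(
    stats_by_circuit: dict[CircuitSpec, float],
    hypothesis: SubgraphHypothesis,
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> float:
    """Cluster mass of a biclique: sum of (statistic - threshold) over members.

    Additive over disjoint member sets; a member below the cluster-forming
    threshold contributes negatively, so the maximizing biclique contains
    exactly the coherently strong circuits.
    """
    return float(
        sum(stats_by_circuit[c] - cluster_threshold for c in hypothesis.member_circuits)
    )


def _group_stats(values: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Vectorized per-group one-sample t statistics.

    ``values`` has shape (..., N) with cells ordered by group; returns shape
    (..., G). Zero-variance groups yield statistic 0.
    """
    sums = np.add.reduceat(values, starts, axis=-1)
    ss = np.add.reduceat(values**2, starts, axis=-1)
    mean = sums / sizes
    var = (ss - sizes * mean**2) / (sizes - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / sizes)
    return np.where(var > 0, t, 0.0)


class SubgraphScan:
    """Permutation scan for the strongest biclique of circuits.

    Parameters
    ----------
    data : DataFrame
        Per-cell values with columns ``input``, ``output``, ``value`` (and
        optionally ``reference``, a matched no-light value per cell used for
        Cohen's d). Entries with fewer than two cells are excluded.

    Build one from an assembled :class:`~clamap.matrix.StrengthMatrix` with
    :meth:`from_matrix`, pick a metric and subtype, then call :meth:`fit`.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        required = {"input", "output", "value"}
        if not required.issubset(data.columns):
            raise ConfigurationError(f"data must have columns {sorted(required)}")
        data = data.copy()
        counts = data.groupby(["input", "output"])["value"].transform("size")
        dropped = data[counts < 2]
        if len(dropped):
            warnings.warn(f"excluding {len(dropped)} cells in entries with n < 2", stacklevel=2)
            data = data[counts >= 2]
        if data.empty:
            raise ConfigurationError("no circuit has n >= 2 cells")
        self.inputs = tuple(sorted(data["input"].unique()))
        self.outputs = tuple(sorted(data["output"].unique()))
        circuits = [CircuitSpec(i, o) for i in self.inputs for o in self.outputs]
        present = {(i, o) for i, o in zip(data["input"], data["output"])}
        missing = [c for c in circuits if (c.input_region, c.output_region) not in present]
        if missing:
            raise ConfigurationError(
                f"biclique scan needs every input x output entry populated; missing {missing[:4]}"
            )
        order = {(c.input_region, c.output_region): k for k, c in enumerate(circuits)}
        data = data.assign(_g=[order[(i, o)] for i, o in zip(data["input"], data["output"])])
        data = data.sort_values("_g", kind="stable").reset_index(drop=True)
        self.data = data
        self.circuits = circuits
        self.sizes = data.groupby("_g")["value"].size().to_numpy()
        self.starts = np.concatenate([[0], np.cumsum(self.sizes)[:-1]])
        self.values = data["value"].to_numpy(float)
        self.reference = data["reference"].to_numpy(float) if "reference" in data.columns else None
        self._masks, self.hypotheses = self._candidate_masks()

    @classmethod
    def from_matrix(cls, matrix: StrengthMatrix, metric: str = "auc", subtype: str = "I") -> "SubgraphScan":
        """Scan one metric/subtype plane of an assembled strength matrix."""
        return cls(matrix.long_values(metric, subtype))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value_col: str = "value",
        input_col: str = "input",
        output_col: str = "output",
        reference_col: str | None = None,
    ) -> "SubgraphScan":
        cols = {input_col: "input", output_col: "output", value_col: "value"}
        if reference_col is not None:
            cols[reference_col] = "reference"
        return cls(df[list(cols)].rename(columns=cols))

    def _candidate_masks(self) -> tuple[np.ndarray, list[SubgraphHypothesis]]:
        """All (2^|inputs|-1) x (2^|outputs|-1) biclique membership masks."""
        n_in, n_out = len(self.inputs), len(self.outputs)
        input_subsets = [
            s for r in range(1, n_in + 1) for s in combinations(range(n_in), r)
        ]
        output_subsets = [
            s for r in range(1, n_out + 1) for s in combinations(range(n_out), r)
        ]
        hypotheses = []
        masks = np.zeros((len(input_subsets) * len(output_subsets), n_in * n_out), dtype=float)
        k = 0
        for si in input_subsets:
            for so in output_subsets:
                for i in si:
                    for o in so:
                        masks[k, i * n_out + o] = 1.0
                hypotheses.append(
                    SubgraphHypothesis(
                        tuple(self.inputs[i] for i in si), tuple(self.outputs[o] for o in so)
                    )
                )
                k += 1
        return masks, hypotheses

    def circuit_statistics(self) -> np.ndarray:
        """Observed per-circuit standardized means (order = self.circuits)."""
        return _group_stats(self.values, self.starts, self.sizes)

    def fit(
        self,
        n_permutations: int = 5000,
        alpha: float = 0.001,
        seed: int | None = None,
        cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
        search: str = "exhaustive",
        batch_size: int = 500,
    ) -> "SubgraphScanResults":
        """Run the scan and the max-statistic permutation calibration.

        ``n_permutations`` must be at least 1/alpha so the significance level
        is resolvable. ``search`` is "exhaustive" (score every biclique;
        default) or "greedy" (grow the observed biclique from the best single
        circuit; the null maximum is still taken over all candidates, which
        is conservative).
        """
        if n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if n_permutations < 1.0 / alpha:
            raise ConfigurationError(
                f"n_permutations={n_permutations} cannot resolve alpha={alpha}; need >= {int(np.ceil(1/alpha))}"
            )
        if search not in ("exhaustive", "greedy"):
            raise ConfigurationError(f"unknown search mode {search!r}")
        rng = np.random.default_rng(seed)
        t_obs = self.circuit_statistics()
        degenerate = [self.circuits[k] for k in np.nonzero(self.sizes < 2)[0]]
        scores_obs = self._masks @ (t_obs - cluster_threshold)
        if search == "exhaustive":
            best_idx = int(np.argmax(scores_obs))
            best_hypothesis = self.hypotheses[best_idx]
            best_score = float(scores_obs[best_idx])
        else:
            best_hypothesis, best_score = self._greedy_search(t_obs, cluster_threshold)

        max_null = np.empty(n_permutations)
        done = 0
        while done < n_permutations:
            b = min(batch_size, n_permutations - done)
            perm = rng.permuted(np.tile(self.values, (b, 1)), axis=1)
            t_perm = _group_stats(perm, self.starts, self.sizes)
            null_scores = (t_perm - cluster_threshold) @ self._masks.T
            max_null[done : done + b] = null_scores.max(axis=1)
            done += b
        exceed = int(np.sum(max_null >= best_score - 1e-12))
        p_fwe = (1 + exceed) / (n_permutations + 1)

        per_circuit_d = self._effect_sizes(best_hypothesis)
        stats_table = pd.DataFrame(
            {
                "input": [c.input_region for c in self.circuits],
                "output": [c.output_region for c in self.circuits],
                "n": self.sizes,
                "statistic": t_obs,
                "in_subgraph": [
                    c in set(best_hypothesis.member_circuits) for c in self.circuits
                ],
            }
        )
        return SubgraphScanResults(
            model=self,
            hypothesis=best_hypothesis,
            score=best_score,
            p_fwe=float(p_fwe),
            alpha=alpha,
            n_permutations=n_permutations,
            seed=seed,
            cluster_threshold=cluster_threshold,
            per_circuit_d=per_circuit_d,
            circuit_table=stats_table,
            degenerate_circuits=degenerate,
            null_max_scores=max_null,
        )

    def _greedy_search(
        self, t_obs: np.ndarray, cluster_threshold: float
    ) -> tuple[SubgraphHypothesis, float]:
        n_out = len(self.outputs)
        t = t_obs - cluster_threshold
        k = int(np.argmax(t))
        cur_in, cur_out = {k // n_out}, {k % n_out}

        def score(si: set[int], so: set[int]) -> float:
            return float(sum(t[i * n_out + o] for i in si for o in so))

        improved = True
        while improved:
            improved = False
            best = (score(cur_in, cur_out), cur_in, cur_out)
            for i in range(len(self.inputs)):
                si = cur_in ^ {i}
                if si and score(si, cur_out) > best[0]:
                    best = (score(si, cur_out), si, cur_out)
            for o in range(n_out):
                so = cur_out ^ {o}
                if so and score(cur_in, so) > best[0]:
                    best = (score(cur_in, so), cur_in, so)
            if best[1] != cur_in or best[2] != cur_out:
                cur_in, cur_out = best[1], best[2]
                improved = True
        hyp = SubgraphHypothesis(
            tuple(self.inputs[i] for i in sorted(cur_in)),
            tuple(self.outputs[o] for o in sorted(cur_out)),
        )
        return hyp, score(cur_in, cur_out)

    def _effect_sizes(self, hypothesis: SubgraphHypothesis) -> dict[CircuitSpec, float]:
        """Cohen's d per member circuit against the matched no-light values
        (one-sample standardized mean when no reference is available)."""
        out: dict[CircuitSpec, float] = {}
        for c in hypothesis.member_circuits:
            k = self.circuits.index(c)
            sl = slice(self.starts[k], self.starts[k] + self.sizes[k])
            vals = self.values[sl]
            try:
                if self.reference is not None:
                    out[c] = cohens_d(vals, self.reference[sl])
                else:
                    out[c] = circuit_statistic(vals) / np.sqrt(vals.size)
            except DegenerateStatisticError:
                out[c] = np.nan
        return out


@dataclass
class SubgraphScanResults:
    """Detected biclique, its FWE-corrected p-value, and diagnostics."""

    model: SubgraphScan
    hypothesis: SubgraphHypothesis
    score: float
    p_fwe: float
    alpha: float
    n_permutations: int
    seed: int | None
    cluster_threshold: float
    per_circuit_d: dict[CircuitSpec, float]
    circuit_table: pd.DataFrame
    degenerate_circuits: list[CircuitSpec] = field(default_factory=list)
    null_max_scores: np.ndarray | None = None

    @property
    def significant(self) -> bool:
        return self.p_fwe <= self.alpha

    def summary(self) -> str:
        lines = [
            "Biclique subgraph scan (max-statistic permutation FWE)",
            "=" * 58,
            f"candidates scored:   {len(self.model.hypotheses)}",
            f"permutations:        {self.n_permutations} (seed={self.seed})",
            f"cluster threshold:   {self.cluster_threshold}",
            f"detected subgraph:   {self.hypothesis.label}",
            f"cluster mass score:  {self.score:.3f}",
            f"p (FWE-corrected):   {self.p_fwe:.4g}"
            + ("  <= alpha" if self.significant else f"  > alpha={self.alpha}"),
            "",
            "member circuits (statistic, Cohen's d):",
        ]
        for c in self.hypothesis.member_circuits:
            row = self.circuit_table[
                (self.circuit_table["input"] == c.input_region)
                & (self.circuit_table["output"] == c.output_region)
            ].iloc[0]
            lines.append(
                f"  {c.label:<22s} t={row['statistic']:7.2f}  d={self.per_circuit_d[c]:6.2f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "input_set": list(self.hypothesis.input_set),
            "output_set": list(self.hypothesis.output_set),
            "member_circuits": [c.label for c in self.hypothesis.member_circuits],
            "score": self.score,
            "p_fwe": self.p_fwe,
            "alpha": self.alpha,
            "significant": self.significant,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "cluster_threshold": self.cluster_threshold,
            "per_circuit_d": {c.label: float(d) for c, d in self.per_circuit_d.items()},
        }


# ---------------------------------------------------------------------------
# subtype comparisons and omnibus test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TypeComparison:
    circuit: CircuitSpec
    statistic: float
    p_value: float
    direction: str  # "II>I", "I>II" or "none"
    all_tied: bool = False


def compare_types(
    values_type_i: np.ndarray,
    values_type_ii: np.ndarray,
    circuit: CircuitSpec,
    alpha: float = 0.05,
    method: str = "exact-mc",
    n_resamples: int = 20_000,
    seed: int | None = 0,
) -> TypeComparison:
    """Two-sided Wilcoxon rank-sum test between subtypes for one circuit.

    Midranks handle ties; fully tied data are flagged and reported as p = 1.
    The default ``exact-mc`` method permutes group labels over the fixed
    midranks (Monte-Carlo exact test) — with the heavily tied binary-response
    data the asymptotic normal approximation is anti-conservative, but it
    remains available as ``method="asymptotic"``.
    """
    x = np.asarray(values_type_i, dtype=float)
    y = np.asarray(values_type_ii, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateStatisticError("subtype comparison requires n >= 2 per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TypeComparison(circuit, x.size * y.size / 2.0, 1.0, "none", all_tied=True)
    u_stat = float(stats.mannwhitneyu(y, x, alternative="two-sided").statistic)
    if method == "asymptotic":
        p = float(stats.mannwhitneyu(y, x, alternative="two-sided", method="asymptotic").pvalue)
    elif method == "exact-mc":
        pooled = np.concatenate([y, x])
        ranks = stats.rankdata(pooled)
        mu = y.size * (pooled.size + 1) / 2.0
        obs = abs(ranks[: y.size].sum() - mu)
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_resamples, pooled.size)), axis=1)[:, : y.size]
        t_null = np.abs(ranks[idx].sum(axis=1) - mu)
        p = float((1 + np.sum(t_null >= obs - 1e-9)) / (n_resamples + 1))
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    direction = "none"
    if p <= alpha:
        direction = "II>I" if y.mean() > x.mean() else "I>II"
    return TypeComparison(circuit, u_stat, p, direction)


def compare_types_table(
    matrix: StrengthMatrix,
    metric: str = "binary",
    alpha: float = 0.05,
    method: str = "exact-mc",
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-circuit subtype comparisons with Benjamini-Hochberg adjustment.

    Raw p-values are the primary report (matching field practice); the BH
    column is supplied alongside for multiplicity-aware reading.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    circuits = [
        CircuitSpec(i, o)
        for i in matrix.cells["input"].unique()
        for o in matrix.cells["output"].unique()
    ]
    circuit_seeds = ss.generate_state(len(circuits))
    for circuit, c_seed in zip(circuits, circuit_seeds):
        vi = matrix.values(metric, "I", circuit.input_region, circuit.output_region)
        vii = matrix.values(metric, "II", circuit.input_region, circuit.output_region)
        if vi.size < 2 or vii.size < 2:
            continue
        cmp = compare_types(vi, vii, circuit, alpha, method=method, seed=int(c_seed))
        rows.append(
            {
                "input": circuit.input_region,
                "output": circuit.output_region,
                "circuit": circuit.label,
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "direction": cmp.direction,
                "all_tied": cmp.all_tied,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_bh"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df


def omnibus_across_circuits(matrix: StrengthMatrix, metric: str = "auc", subtype: str = "I") -> tuple[float, float]:
    """Kruskal-Wallis H across circuits (midrank tie correction, chi-square
    reference with groups-1 df). Returns (H, p)."""
    groups = []
    for inp in matrix.cells["input"].unique():
        for out in matrix.cells["output"].unique():
            vals = matrix.values(metric, subtype, inp, out)
            if vals.size >= 2:
                groups.append(vals)
    if len(groups) < 2:
        raise ConfigurationError("omnibus test requires >= 2 circuits with n >= 2")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
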