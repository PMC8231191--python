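"""Upstream regulator analysis (URA).

Each (drug, regulator) pair is scored on two axes:

* **overlap significance** — the hypergeometric upper-tail probability that at
  least the observed number of the regulator's targets fall in the drug's DEG
  set, given the measured-gene universe;
* **activation z-score** — a direction-consistency statistic over the
  differentially expressed targets,

      z = sum_t w_t * sign_t * dir_t / sqrt(sum_t w_t^2),

  where sign_t is the edge sign (+1 activating, -1 inhibiting), dir_t the
  target's DE direction and w_t the edge weight. z > 2 predicts the regulator
  is Activated under the drug, z < -2 Inhibited (strict thresholds).

A regulator need not itself be measured or differentially expressed for its
program to score: its own log-ratio is reported when available and left absent
otherwise.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dge import EmptyUniverseError
from .kb import RegulatorKB

ACTIVATED = "Activated"
INHIBITED = "Inhibited"
NO_STATE = "None"

URA_COLUMNS = ["drug", "regulator", "n_universe", "n_targets_in_universe",
               "n_degs", "n_overlap", "activation_z", "p_overlap",
               "predicted_state", "regulator_log2_ratio",
               "regulator_fold_change"]


def overlap_pvalue(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): the p-value of overlap.

    N measured genes, K regulator targets among them, n DEGs, k targets that
    are DEGs. Exact tail computed in a numerically stable way; returns a value
    in (0, 1].
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    if k < max(0, K + n - N):
        raise ValueError(f"k={k} below the support minimum {max(0, K + n - N)}")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    if p <= 0.0:  # extreme underflow; recover from the log tail
        p = float(math.exp(hypergeom.logsf(k - 1, N, K, n)))
    return min(p, 1.0) if p > 0 else float(np.finfo(float).tiny)


def activation_zscore(edges: pd.DataFrame, deg_directions: dict) -> float:
    """Direction-consistency z over the regulator's differentially expressed targets.

    ``edges`` is an edge table (columns target, sign, weight) already
    restricted to the measured universe; ``deg_directions`` maps DEG gene ids
    to +1/-1. Targets that are not DEGs contribute nothing; returns NaN when
    the overlap is empty.
    """
    bad = [g for g, d in deg_directions.items() if d not in (1, -1)]
    if bad:
        raise ValueError(
            f"DEG directions must be +1/-1; offending genes: {bad[:3]}")
    in_overlap = edges["target"].map(deg_directions.__contains__)
    sub = edges[in_overlap]
    if len(sub) == 0:
        return float("nan")
    w = sub["weight"].to_numpy(dtype=float)
    s = sub["sign"].to_numpy(dtype=float)
    d = sub["target"].map(deg_directions).to_numpy(dtype=float)
    return float(np.sum(w * s * d) / math.sqrt(np.sum(w * w)))


def predict_state(z, threshold: float = 2.0) -> str:
    """Activated iff z > threshold, Inhibited iff z < -threshold (strict)."""
    if z is None or (isinstance(z, float) and math.isnan(z)):
        return NO_STATE
    if z > threshold:
        return ACTIVATED
    if z < -threshold:
        return INHIBITED
    return NO_STATE


def signed_fold_change(log2_ratio: float) -> float:
    """Signed linear fold change, the screen's reporting convention.

    +2.0 means 2-fold up, -2.0 means 2-fold down; sign carries the direction
    and the magnitude is 2**|log2_ratio|.
    """
    if log2_ratio is None or math.isnan(log2_ratio):
        return float("nan")
    if log2_ratio == 0:
        return 1.0
    return math.copysign(2.0 ** abs(log2_ratio), log2_ratio)


def run_ura(deg_table: pd.DataFrame, kb: RegulatorKB,
            alpha_deg: float = 0.05, *, z_state_threshold: float = 2.0,
            adjust_overlap_p: bool = False) -> pd.DataFrame:
    """Score every (drug, regulator) pair with >= 1 target in the measured universe.

    The universe for each drug is the gene set present in ``deg_table`` for
    that drug; the DEG set is the genes with p_adj < ``alpha_deg``. Direction
    scoring uses the robust-z sign, excluding exact zeros. When
    ``adjust_overlap_p`` is set, overlap p-values are BH-adjusted across
    regulators within each drug (off by default: the raw p < 0.05 convention).
    """
    if deg_table.empty:
        raise EmptyUniverseError("empty DEG table: no measured genes")
    results = []
    for drug, sub in deg_table.groupby("drug", sort=False):
        universe = sub["gene"].tolist()
        n_universe = len(universe)
        if n_universe == 0:
            raise EmptyUniverseError(f"drug {drug!r} has an empty universe")
        degs = sub[sub["p_adj"] < alpha_deg]
        directions = {
            g: int(d) for g, d in zip(degs["gene"], degs["direction"])
            if d != 0}
        deg_genes = set(degs["gene"])
        own = sub.set_index("gene")["log2_ratio"]
        for regulator in kb.regulators:
            edges = kb.targets_of(regulator, universe)
            K = len(edges)
            if K == 0:
                continue
            k = int(edges["target"].isin(deg_genes).sum())
            p = overlap_pvalue(n_universe, K, len(deg_genes), k)
            z = activation_zscore(edges, directions)
            own_lr = float(own[regulator]) if regulator in own.index else float("nan")
            results.append({
                "drug": drug,
                "regulator": regulator,
                "n_universe": n_universe,
                "n_targets_in_universe": K,
                "n_degs": len(deg_genes),
                "n_overlap": k,
                "activation_z": z,
                "p_overlap": p,
                "predicted_state": predict_state(z, z_state_threshold),
                "regulator_log2_ratio": own_lr,
                "regulator_fold_change": signed_fold_change(own_lr),
            })
    out = pd.DataFrame(results, columns=URA_COLUMNS)
    if adjust_overlap_p and len(out):
        from .dge import bh_adjust
        out["p_overlap"] = (
            out.groupby("drug")["p_overlap"]
            .transform(lambda p: bh_adjust(p.to_numpy())))
    return out


def write_ura_table(ura: pd.DataFrame, path) -> None:
    ura.to_csv(path, sep="\t", index=False)


def read_ura_table(path) -> pd.DataFrame:
    ura = pd.read_csv(path, sep="\t", dtype={"drug": str, "regulator": str})
    missing = set(URA_COLUMNS) - set(ura.columns)
    if missing:
        raise ValueError(f"URA table missing columns: {sorted(missing)}")
    return ura
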