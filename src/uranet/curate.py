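"""Robust-network curation and DEG prioritization.

A scored regulator program is curated by dropping targets that are not
significant (p_adj >= 0.05) and counting how many of the survivors moved in
the direction the activation z-score predicts (through the edge sign). A
network is *robust* when it keeps at least ``min_consistent_targets``
direction-consistent significant targets, |activation z| exceeds the state
threshold and the overlap p-value is significant. Genes belonging to at least
one robust network form the high-confidence ("network") tier of the
prioritized DEG list; all other DEGs are "singleton" tier.

The regulator's own expression may agree with the prediction (concordant),
oppose it (discordant — e.g. a regulator called Inhibited while itself
upregulated, because its targets moved up) or be unmeasured (unknown).
Discordance does not veto robustness: the program's evidence lives in the
targets, not the regulator's own transcript.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kb import RegulatorKB
from .ura import ACTIVATED, INHIBITED, NO_STATE

CONCORDANT = "concordant"
DISCORDANT = "discordant"
UNKNOWN = "unknown"

NETWORK_COLUMNS = ["drug", "regulator", "n_significant", "n_consistent",
                   "activation_z", "p_overlap", "predicted_state", "robust",
                   "regulator_concordance", "retained_targets"]

PRIORITIZED_COLUMNS = ["drug", "gene", "priority_tier", "member_networks",
                       "best_abs_activation_z", "robust_z", "p_adj"]


@dataclass
class CuratedNetwork:
    drug: str
    regulator: str
    retained_targets: pd.DataFrame  # gene, sign, direction, robust_z, p_adj
    n_significant: int
    n_consistent: int
    activation_z: float
    p_overlap: float
    predicted_state: str
    robust: bool
    regulator_own_log2_ratio: float = float("nan")
    regulator_concordance: str = UNKNOWN
    member_genes: set = field(default_factory=set)


def curate_network(ura_row, deg_table: pd.DataFrame, kb: RegulatorKB, *,
                   alpha: float = 0.05, min_consistent_targets: int = 5,
                   z_state_threshold: float = 2.0,
                   p_overlap_threshold: float = 0.05,
                   count_rule: str = "consistent") -> CuratedNetwork:
    """Curate one scored (drug, regulator) program.

    ``count_rule`` selects what the >= ``min_consistent_targets`` requirement
    counts: ``"consistent"`` (significant AND direction-consistent targets,
    the default) or ``"significant"`` (significance alone).
    """
    if count_rule not in ("consistent", "significant"):
        raise ValueError(f"unknown count_rule: {count_rule!r}")
    drug = ura_row["drug"]
    regulator = ura_row["regulator"]
    z = float(ura_row["activation_z"])
    p_overlap = float(ura_row["p_overlap"])

    sub = deg_table[deg_table["drug"] == drug].set_index("gene")
    edges = kb.targets_of(regulator, sub.index)
    stats = sub.loc[edges["target"], ["direction", "robust_z", "p_adj"]]
    merged = pd.DataFrame({
        "gene": edges["target"].to_numpy(),
        "sign": edges["sign"].to_numpy(),
        "direction": stats["direction"].to_numpy(dtype=int),
        "robust_z": stats["robust_z"].to_numpy(dtype=float),
        "p_adj": stats["p_adj"].to_numpy(dtype=float),
    })
    retained = merged[merged["p_adj"] < alpha].reset_index(drop=True)

    z_sign = 0 if (math.isnan(z) or z == 0) else (1 if z > 0 else -1)
    n_consistent = (
        0 if z_sign == 0
        else int((retained["sign"] * retained["direction"] == z_sign).sum()))
    n_counted = len(retained) if count_rule == "significant" else n_consistent
    robust = (n_counted >= min_consistent_targets
              and abs(z) > z_state_threshold
              and p_overlap < p_overlap_threshold) if not math.isnan(z) else False

    net = CuratedNetwork(
        drug=drug, regulator=regulator, retained_targets=retained,
        n_significant=len(retained), n_consistent=n_consistent,
        activation_z=z, p_overlap=p_overlap,
        predicted_state=ura_row["predicted_state"], robust=robust,
        regulator_own_log2_ratio=float(ura_row.get("regulator_log2_ratio",
                                                   float("nan"))),
        member_genes=set(retained["gene"]))
    net.regulator_concordance = regulator_concordance(net)
    return net


def regulator_concordance(net: CuratedNetwork) -> str:
    """Does the regulator's own expression change agree with its predicted state?"""
    own = net.regulator_own_log2_ratio
    if own is None or math.isnan(own) or own == 0:
        return UNKNOWN
    if net.predicted_state == NO_STATE:
        return UNKNOWN
    state_sign = 1 if net.predicted_state == ACTIVATED else -1
    return CONCORDANT if (own > 0) == (state_sign > 0) else DISCORDANT


def curate_all(ura_table: pd.DataFrame, deg_table: pd.DataFrame,
               kb: RegulatorKB, **kwargs) -> list[CuratedNetwork]:
    return [curate_network(row, deg_table, kb, **kwargs)
            for _, row in ura_table.iterrows()]


def networks_to_frame(nets: list[CuratedNetwork]) -> pd.DataFrame:
    rows = []
    for net in nets:
        rows.append({
            "drug": net.drug, "regulator": net.regulator,
            "n_significant": net.n_significant,
            "n_consistent": net.n_consistent,
            "activation_z": net.activation_z, "p_overlap": net.p_overlap,
            "predicted_state": net.predicted_state, "robust": net.robust,
            "regulator_concordance": net.regulator_concordance,
            "retained_targets": ",".join(net.retained_targets["gene"]),
        })
    return pd.DataFrame(rows, columns=NETWORK_COLUMNS)


def prioritize_degs(deg_table: pd.DataFrame,
                    curated: list[CuratedNetwork]) -> pd.DataFrame:
    """Annotate every called DEG with its robust-network memberships and rank it.

    Tier ``network`` requires membership in at least one *robust* network.
    Within each tier rows are ordered by |activation z| of the best member
    network (descending), then overlap p-value (ascending), then gene id; the
    order is total and deterministic.
    """
    by_drug: dict[str, list[CuratedNetwork]] = {}
    for net in curated:
        by_drug.setdefault(net.drug, []).append(net)

    rows = []
    for _, rec in deg_table[deg_table["is_deg"]].iterrows():
        drug, gene = rec["drug"], rec["gene"]
        members = [net for net in by_drug.get(drug, ())
                   if gene in net.member_genes]
        robust_members = [net for net in members if net.robust]
        tier = "network" if robust_members else "singleton"
        ranked = robust_members or members
        if ranked:
            best = max(ranked, key=lambda n: (abs(n.activation_z),
                                              -n.p_overlap))
            best_z, best_p = abs(best.activation_z), best.p_overlap
        else:
            best_z, best_p = 0.0, float("inf")
        rows.append({
            "drug": drug, "gene": gene, "priority_tier": tier,
            "member_networks": ";".join(
                f"{n.regulator}:{n.activation_z:g}" for n in members),
            "best_abs_activation_z": best_z, "_best_p": best_p,
            "robust_z": rec["robust_z"], "p_adj": rec["p_adj"],
        })
    out = pd.DataFrame(rows, columns=PRIORITIZED_COLUMNS + ["_best_p"])
    if len(out):
        out["_tier_rank"] = np.where(out["priority_tier"] == "network", 0, 1)
        out = out.sort_values(
            by=["drug", "_tier_rank", "best_abs_activation_z", "_best_p",
                "gene"],
            ascending=[True, True, False, True, True],
            kind="mergesort").reset_index(drop=True)
        out = out.drop(columns=["_tier_rank"])
    return out[PRIORITIZED_COLUMNS]


def write_networks(nets: list[CuratedNetwork], path) -> None:
    networks_to_frame(nets).to_csv(path, sep="\t", index=False)


def write_prioritized(prioritized: pd.DataFrame, path) -> None:
    prioritized.to_csv(path, sep="\t", index=False)
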