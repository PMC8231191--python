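"""Synthetic drug-screen generator with known ground truth.

Emulates a single-replicate perturbation screen: every gene has a baseline
log2 abundance shared across conditions, each (gene, drug) observation adds
independent Gaussian noise on the log2 scale, and signal is planted two ways —

* **regulator programs**: a regulator is activated (+1) or inhibited (-1) in
  one drug's column and every one of its targets shifts by
  ``effect_size * edge_sign * activation_sign``;
* **singleton DEGs**: genes outside every program shift by the same
  ``effect_size`` with a random sign, so the two strata differ only in
  network membership.

The matrix is emitted in linear CPM (2**x - 1, the inverse of the DE stage's
log2(cpm + 1) transform) so planted log2 shifts survive the round trip
exactly. All randomness derives from one master seed via named substreams,
making every output reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .kb import RegulatorKB, KB_COLUMNS

#: substream tags so each stage draws from an independent, named stream
_KB_STREAM, _SCREEN_STREAM = 1, 2

#: spread (log2 units) of per-gene baselines around baseline_mean_log2cpm
_BASELINE_SD = 1.0


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Screen design: defaults give a 2000-gene, 20-drug panel with ten planted
    8-target programs, ten singleton DEGs per drug, and shifts of five noise SDs."""

    n_genes: int = 2000
    n_drugs: int = 20
    n_regulators: int = 10
    targets_per_regulator: int = 8
    frac_inhibiting_edges: float = 0.25
    effect_size: float = 2.5       # log2 units
    noise_sd: float = 0.5          # log2 units
    n_singleton_degs_per_drug: int = 10
    baseline_mean_log2cpm: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_drugs < 1:
            raise InvalidConfigError("n_genes and n_drugs must be positive")
        if self.n_regulators < 0 or self.targets_per_regulator < 1:
            raise InvalidConfigError(
                "n_regulators must be >= 0 and targets_per_regulator >= 1")
        if self.n_regulators * self.targets_per_regulator > self.n_genes:
            raise InvalidConfigError(
                f"{self.n_regulators} regulators x {self.targets_per_regulator} "
                f"targets demand more distinct genes than n_genes={self.n_genes}")
        if not 0 <= self.frac_inhibiting_edges <= 1:
            raise InvalidConfigError("frac_inhibiting_edges must be in [0, 1]")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise InvalidConfigError("effect_size must be >= 0")
        if self.n_singleton_degs_per_drug < 0:
            raise InvalidConfigError("n_singleton_degs_per_drug must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: programs as (drug, regulator, +/-1), DEGs as
    (drug, gene, direction); singletons are the planted DEGs outside the KB."""

    active_programs: set = field(default_factory=set)
    planted_deg_set: set = field(default_factory=set)
    singleton_deg_set: set = field(default_factory=set)

    @property
    def planted_pairs(self) -> set:
        return {(d, g) for d, g, _ in self.planted_deg_set}


def gene_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes - 1))
    return [f"G{i:0{width}d}" for i in range(config.n_genes)]


def drug_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_drugs - 1))
    return [f"drug{i:0{width}d}" for i in range(config.n_drugs)]


def regulator_ids(config: SimulationConfig) -> list[str]:
    return [f"REG{i:02d}" for i in range(config.n_regulators)]


def generate_kb(config: SimulationConfig) -> RegulatorKB:
    """Draw a knowledge base of disjoint target programs, signs per
    frac_inhibiting_edges; deterministic in the config seed."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _KB_STREAM]))
    genes = np.array(gene_ids(config))
    n_edges = config.n_regulators * config.targets_per_regulator
    chosen = rng.choice(config.n_genes, size=n_edges, replace=False)
    rows = []
    for r, reg in enumerate(regulator_ids(config)):
        block = chosen[r * config.targets_per_regulator:
                       (r + 1) * config.targets_per_regulator]
        signs = np.where(
            rng.random(config.targets_per_regulator)
            < config.frac_inhibiting_edges, -1, 1)
        rows.extend((reg, genes[t], int(s), 1.0)
                    for t, s in zip(block, signs))
    return RegulatorKB(pd.DataFrame(rows, columns=KB_COLUMNS))


def simulate_screen(config: SimulationConfig,
                    kb: RegulatorKB | None = None
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the CPM matrix and its ground truth.

    Each regulator is activated or inhibited (random sign) in exactly one
    drug, assigned round-robin; singleton genes are drawn per drug from genes
    untouched by the knowledge base. With effect_size 0 nothing is planted and
    the screen is pure null.
    """
    if kb is None:
        kb = generate_kb(config)
    genes = gene_ids(config)
    drugs = drug_ids(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    unknown = kb.targets - set(genes)
    if unknown:
        raise InvalidConfigError(
            f"KB targets outside the gene universe: {sorted(unknown)[:3]}")

    root = np.random.SeedSequence([config.seed, _SCREEN_STREAM])
    setup_rng = np.random.default_rng(root)
    baselines = (config.baseline_mean_log2cpm
                 + _BASELINE_SD * setup_rng.standard_normal(config.n_genes))

    # program assignment: regulator r acts in drug r % n_drugs
    program_signs = setup_rng.choice([-1, 1], size=len(kb.regulators))
    programs = [(drugs[r % config.n_drugs], reg, int(program_signs[r]))
                for r, reg in enumerate(kb.regulators)]

    kb_genes = kb.targets
    free = [g for g in genes if g not in kb_genes]
    singleton_choices = {}
    for d, drug in enumerate(drugs):
        n_single = min(config.n_singleton_degs_per_drug, len(free))
        picked = setup_rng.choice(len(free), size=n_single, replace=False)
        dirs = setup_rng.choice([-1, 1], size=n_single)
        singleton_choices[drug] = [(free[i], int(s))
                                   for i, s in zip(picked, dirs)]

    truth = GroundTruth()
    shifts = np.zeros((config.n_genes, config.n_drugs))
    if config.effect_size > 0:
        for drug, reg, sigma in programs:
            truth.active_programs.add((drug, reg, sigma))
            d = drugs.index(drug)
            for _, edge in kb.targets_of(reg).iterrows():
                direction = int(edge["sign"]) * sigma
                shifts[gene_index[edge["target"]], d] += (
                    config.effect_size * direction)
                truth.planted_deg_set.add((drug, edge["target"], direction))
        for drug, picks in singleton_choices.items():
            d = drugs.index(drug)
            for gene, direction in picks:
                shifts[gene_index[gene], d] += config.effect_size * direction
                truth.planted_deg_set.add((drug, gene, direction))
                truth.singleton_deg_set.add((drug, gene, direction))

    # per-drug noise substreams keep columns independent and reproducible
    log2 = baselines[:, None] + shifts
    for d in range(config.n_drugs):
        drug_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, _SCREEN_STREAM, d]))
        log2[:, d] += config.noise_sd * drug_rng.standard_normal(config.n_genes)

    cpm = np.maximum(np.exp2(log2) - 1.0, 0.0)
    matrix = pd.DataFrame(cpm, index=pd.Index(genes, name="gene"),
                          columns=drugs)
    return matrix, truth


def write_ground_truth(truth: GroundTruth, programs_path, planted_path) -> None:
    progs = pd.DataFrame(sorted(truth.active_programs),
                         columns=["drug", "regulator", "activation_sign"])
    progs.to_csv(programs_path, sep="\t", index=False)
    singles = truth.singleton_deg_set
    planted = pd.DataFrame(
        [(d, g, s, (d, g, s) in singles)
         for d, g, s in sorted(truth.planted_deg_set)],
        columns=["drug", "gene", "direction", "is_singleton"])
    planted.to_csv(planted_path, sep="\t", index=False)


def program_recovery_experiment(config: SimulationConfig, n_reps: int, *,
                                alpha: float = 0.05,
                                min_consistent_targets: int = 5,
                                z_state_threshold: float = 2.0,
                                p_overlap_threshold: float = 0.05
                                ) -> pd.DataFrame:
    """How often are planted programs recovered as robust networks with the
    right sign?

    Per replicate (seeded ``config.seed + rep``) returns the planted program
    count, how many came back robust, and how many of those carried the
    correct Activated/Inhibited prediction.
    """
    from .dge import call_degs
    from .ura import run_ura, ACTIVATED, INHIBITED
    from .curate import curate_all

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for rep in range(n_reps):
        cfg = SimulationConfig(**{**asdict(config), "seed": config.seed + rep})
        kb = generate_kb(cfg)
        matrix, truth = simulate_screen(cfg, kb)
        degs = call_degs(matrix, alpha)
        ura = run_ura(degs, kb, alpha, z_state_threshold=z_state_threshold)
        nets = curate_all(ura, degs, kb, alpha=alpha,
                          min_consistent_targets=min_consistent_targets,
                          z_state_threshold=z_state_threshold,
                          p_overlap_threshold=p_overlap_threshold)
        by_key = {(net.drug, net.regulator): net for net in nets}
        n_robust = n_correct = 0
        for drug, reg, sigma in truth.active_programs:
            net = by_key.get((drug, reg))
            if net is not None and net.robust:
                n_robust += 1
                expected = ACTIVATED if sigma > 0 else INHIBITED
                n_correct += net.predicted_state == expected
        rows.append({"rep": rep, "seed": cfg.seed,
                     "n_programs": len(truth.active_programs),
                     "n_robust": n_robust,
                     "n_robust_correct_sign": n_correct})
    return pd.DataFrame(rows)


def validation_rate_experiment(config: SimulationConfig, n_reps: int, *,
                               alpha: float = 0.05,
                               min_consistent_targets: int = 5,
                               z_state_threshold: float = 2.0,
                               p_overlap_threshold: float = 0.05
                               ) -> pd.DataFrame:
    """Contrast true-positive rates of network-tier vs singleton-tier DEG calls.

    Runs the full pipeline on ``n_reps`` independently seeded screens. Per
    replicate it reports the fraction of called DEGs that were actually
    planted, separately for DEGs inside robust curated networks ("network"
    tier) and outside them ("singleton" tier), plus the ratio of the two
    rates. A stratum with zero calls yields NaN (absent), never zero. A final
    row labelled ``mean`` averages the available values.
    """
    from .dge import call_degs
    from .ura import run_ura
    from .curate import curate_all, prioritize_degs

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for rep in range(n_reps):
        cfg = SimulationConfig(**{**asdict(config), "seed": config.seed + rep})
        kb = generate_kb(cfg)
        matrix, truth = simulate_screen(cfg, kb)
        degs = call_degs(matrix, alpha)
        ura = run_ura(degs, kb, alpha, z_state_threshold=z_state_threshold)
        nets = curate_all(ura, degs, kb, alpha=alpha,
                          min_consistent_targets=min_consistent_targets,
                          z_state_threshold=z_state_threshold,
                          p_overlap_threshold=p_overlap_threshold)
        prioritized = prioritize_degs(degs, nets)
        planted = truth.planted_pairs
        strata = {}
        for tier in ("network", "singleton"):
            sub = prioritized[prioritized["priority_tier"] == tier]
            strata[tier] = (
                float(np.mean([(d, g) in planted
                               for d, g in zip(sub["drug"], sub["gene"])]))
                if len(sub) else float("nan"))
        tpr_net, tpr_single = strata["network"], strata["singleton"]
        ratio = (tpr_net / tpr_single
                 if np.isfinite(tpr_net) and np.isfinite(tpr_single)
                 and tpr_single > 0 else float("nan"))
        rows.append({"rep": str(rep), "seed": cfg.seed,
                     "n_network_calls": int(
                         (prioritized["priority_tier"] == "network").sum()),
                     "n_singleton_calls": int(
                         (prioritized["priority_tier"] == "singleton").sum()),
                     "tpr_network": tpr_net, "tpr_singleton": tpr_single,
                     "tpr_ratio": ratio})
    out = pd.DataFrame(rows)
    mean_row = {"rep": "mean", "seed": config.seed}
    for col in ("n_network_calls", "n_singleton_calls", "tpr_network",
                "tpr_singleton", "tpr_ratio"):
        vals = out[col].to_numpy(dtype=float)
        mean_row[col] = (float(np.nanmean(vals))
                         if np.isfinite(vals).any() else float("nan"))
    return pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)
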