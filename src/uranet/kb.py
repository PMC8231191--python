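"""Signed regulator->target knowledge base.

A knowledge base is a collection of directed edges, each annotating that a
regulator (transcription factor, kinase, drug, ...) activates (+1) or inhibits
(-1) a target gene, optionally with a positive confidence weight. Gene and
regulator identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

_SIGN_TOKENS = {
    "+1": 1, "1": 1, "a": 1, "activating": 1, "activation": 1,
    "-1": -1, "i": -1, "inhibiting": -1, "inhibition": -1,
}

KB_COLUMNS = ["regulator", "target", "sign", "weight"]


class KBValidationError(ValueError):
    pass


def _normalize_sign(token, line: int | None = None) -> int:
    key = str(token).strip().lower()
    if key in _SIGN_TOKENS:
        return _SIGN_TOKENS[key]
    loc = f" at line {line}" if line is not None else ""
    raise KBValidationError(f"unknown sign token {token!r}{loc}")


@dataclass(frozen=True)
class RegulatorEdge:
    regulator: str
    target: str
    sign: int = 1
    weight: float = 1.0

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise KBValidationError(
                f"edge sign must be +1 or -1, got {self.sign!r}")
        if not self.weight > 0:
            raise KBValidationError(
                f"edge weight must be > 0, got {self.weight!r}")
        if self.regulator == self.target:
            raise KBValidationError(
                f"self-edge not allowed: {self.regulator!r}")


@dataclass
class RegulatorKB:
    """Validated edge set with a regulator index for fast target lookup."""

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=KB_COLUMNS))

    def __post_init__(self):
        df = self.edges
        missing = set(KB_COLUMNS[:3]) - set(df.columns)
        if missing:
            raise KBValidationError(f"KB missing columns: {sorted(missing)}")
        df = df.copy()
        if "weight" not in df.columns:
            df["weight"] = 1.0
        df["weight"] = df["weight"].fillna(1.0).astype(float)
        df["regulator"] = df["regulator"].astype(str)
        df["target"] = df["target"].astype(str)
        df["sign"] = df["sign"].astype(int)
        bad = ~df["sign"].isin([1, -1])
        if bad.any():
            raise KBValidationError(
                f"edge signs must be +1 or -1, got {df.loc[bad, 'sign'].iloc[0]}")
        if (df["weight"] <= 0).any():
            raise KBValidationError("edge weights must be > 0")
        self_edges = df["regulator"] == df["target"]
        if self_edges.any():
            raise KBValidationError(
                f"self-edge not allowed: {df.loc[self_edges, 'regulator'].iloc[0]!r}")
        dup = df.duplicated(subset=["regulator", "target"])
        if dup.any():
            r, t = df.loc[dup, ["regulator", "target"]].iloc[0]
            raise KBValidationError(f"duplicate edge ({r!r}, {t!r})")
        self.edges = df[KB_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_edges(cls, edges: list[RegulatorEdge]) -> "RegulatorKB":
        return cls(pd.DataFrame(
            [(e.regulator, e.target, e.sign, e.weight) for e in edges],
            columns=KB_COLUMNS))

    @property
    def regulators(self) -> list[str]:
        return list(dict.fromkeys(self.edges["regulator"]))

    @property
    def targets(self) -> set[str]:
        return set(self.edges["target"])

    def __len__(self) -> int:
        return len(self.edges)

    def targets_of(self, regulator: str, universe=None) -> pd.DataFrame:
        """Edges of one regulator, optionally restricted to a measured-gene universe.

        Row order is stable (KB order). An unknown regulator yields an empty
        edge list with a warning rather than an error, so screens can be scored
        against knowledge bases that extend past the measured genome.
        """
        if regulator not in set(self.edges["regulator"]):
            warnings.warn(f"regulator {regulator!r} not in knowledge base",
                          stacklevel=2)
            return self.edges.iloc[0:0].copy()
        sub = self.edges[self.edges["regulator"] == regulator]
        if universe is not None:
            universe = set(universe)
            sub = sub[sub["target"].isin(universe)]
        return sub.reset_index(drop=True)


def read_kb(path) -> RegulatorKB:
    """Parse a KB TSV with header columns regulator, target, sign[, weight]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"regulator", "target", "sign"} - set(df.columns)
    if missing:
        raise KBValidationError(
            f"KB file {path} missing columns: {sorted(missing)}")
    # +2: header occupies line 1, data starts at line 2
    df["sign"] = [
        _normalize_sign(tok, line=i + 2) for i, tok in enumerate(df["sign"])]
    if "weight" in df.columns:
        df["weight"] = pd.to_numeric(df["weight"]).fillna(1.0)
    else:
        df["weight"] = 1.0
    return RegulatorKB(df)


def write_kb(kb: RegulatorKB, path) -> None:
    kb.edges.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> RegulatorKB:
    """Import GMT gene sets as all-activating, unit-weight regulator edges.

    GMT rows are ``name<TAB>description<TAB>member...``; the format carries no
    edge signs, so every edge is imported as activating.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise KBValidationError(
                    f"GMT line {lineno}: expected name, description, members")
            name, _desc, *members = parts
            for m in members:
                if m:
                    rows.append((name, m, 1, 1.0))
    return RegulatorKB(pd.DataFrame(rows, columns=KB_COLUMNS))
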