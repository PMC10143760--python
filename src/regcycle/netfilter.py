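"""Rule-based screen for candidate delay regulators in a signed network.

The model predicts an intermediary protein (REG) between AMPK and the
autophagy initiation machinery.  Given a signed, directed protein-
interaction table, real proteins are scored against the three REG criteria:

1. induced by AMPK              (activation edge  AMPK -> X)
2. promotes ULK1                (activation edge  X -> ULK1)
3. down-regulates mTOR(C1)      (inhibition edge  X -> mTOR)

Candidates satisfy at least ``min_count`` criteria (2 by default).  Their
upstream regulatory layer is then filtered under a sign-consistency rule:
an upstream regulator must not flip the net sign a criterion requires, so
only activating incoming edges onto a candidate survive.

Tables are pandas DataFrames with columns ``source, target, sign, layer,
evidence`` (sign: activation/inhibition; layer: direct/additional;
evidence: experimental/predicted).  Identifiers are plain case-sensitive
strings; mapping between identifier schemes is the caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "CandidateScore", "DiscardReport",
           "validate_records", "score_criteria", "select_candidates",
           "upstream_expand", "read_edge_table", "write_edge_table",
           "write_sif"]

REQUIRED_COLUMNS = ("source", "target", "sign", "layer", "evidence")
SIGNS = ("activation", "inhibition")
LAYERS = ("direct", "additional")
EVIDENCE = ("experimental", "predicted")

CRITERIA = ("induced_by_ampk", "activates_ulk1", "inhibits_mtor")


@dataclass(frozen=True)
class CandidateScore:
    protein: str
    induced_by_ampk: bool
    activates_ulk1: bool
    inhibits_mtor: bool
    evidence: dict = field(default_factory=dict, hash=False, compare=False)

    @property
    def count(self) -> int:
        return int(self.induced_by_ampk) + int(self.activates_ulk1) \
            + int(self.inhibits_mtor)

    def flags(self) -> dict:
        return {c: getattr(self, c) for c in CRITERIA}


@dataclass
class DiscardReport:
    unsigned: int = 0
    sign_inconsistent: int = 0
    not_incoming: int = 0

    @property
    def total(self) -> int:
        return self.unsigned + self.sign_inconsistent + self.not_incoming


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"edge table missing columns {missing}")
    bad = records.loc[~records["sign"].isin(SIGNS + ("unknown",)), "sign"]
    if len(bad):
        raise ValueError(f"invalid sign values: {sorted(bad.unique())}")
    return records


def _edge_supported(edges: pd.DataFrame, required_sign: str):
    """Whether the records for one ordered pair support ``required_sign``.

    Experimental annotation wins over predicted: a predicted edge of the
    required sign is overruled by an experimental edge of the opposite
    sign; conflicting records count only when at least one experimental
    record carries the required sign.  Returns (supported, evidence_class).
    """
    signs = edges["sign"]
    ev = edges["evidence"]
    exp_req = ((signs == required_sign) & (ev == "experimental")).any()
    exp_opp = ((signs != required_sign) & (signs.isin(SIGNS))
               & (ev == "experimental")).any()
    pred_req = ((signs == required_sign) & (ev == "predicted")).any()
    if exp_req:
        return True, "experimental"
    if pred_req and not exp_opp:
        return True, "predicted"
    return False, None


def score_criteria(records: pd.DataFrame, hub_ids: dict) -> list[CandidateScore]:
    """Score every non-hub protein in the table against the three criteria.

    ``hub_ids`` maps the roles ``ampk``, ``ulk1``, ``mtor`` to the
    identifiers used in the table.  Scoring is invariant to record order
    and duplication.  Self-loops are tolerated (they can never satisfy a
    criterion because hubs are excluded from candidacy).
    """
    records = validate_records(records)
    for role in ("ampk", "ulk1", "mtor"):
        if role not in hub_ids:
            raise KeyError(f"hub_ids missing {role!r}")
    ampk, ulk1, mtor = hub_ids["ampk"], hub_ids["ulk1"], hub_ids["mtor"]
    hubs = {ampk, ulk1, mtor}
    present = set(records["source"]) | set(records["target"])
    if not hubs & present:
        raise ValueError("none of the hub identifiers appear in the table")

    by_pair = dict(tuple(records.groupby(["source", "target"], sort=False)))

    def support(src, dst, sign):
        edges = by_pair.get((src, dst))
        if edges is None:
            return False, None
        return _edge_supported(edges, sign)

    scores = []
    for prot in sorted(present - hubs):
        c1, e1 = support(ampk, prot, "activation")
        c2, e2 = support(prot, ulk1, "activation")
        c3, e3 = support(prot, mtor, "inhibition")
        ev = {name: e for name, e, hit in
              zip(CRITERIA, (e1, e2, e3), (c1, c2, c3)) if hit}
        scores.append(CandidateScore(prot, c1, c2, c3, ev))
    return scores


def select_candidates(scores: list[CandidateScore],
                      min_count: int = 2) -> list[CandidateScore]:
    """Proteins meeting at least ``min_count`` criteria, best first."""
    if min_count not in (1, 2, 3):
        raise ValueError("min_count must be 1, 2 or 3")
    hits = [s for s in scores if s.count >= min_count]
    return sorted(hits, key=lambda s: (-s.count, s.protein))


def upstream_expand(records: pd.DataFrame,
                    candidates: list[CandidateScore],
                    activator_rule_only: bool = False,
                    ) -> tuple[pd.DataFrame, DiscardReport]:
    """Sign-consistent upstream layer of the selected candidates.

    Keeps only incoming directed edges U -> X onto candidates whose sign,
    composed with X's criterion effects, preserves each satisfied
    criterion's required net sign.  Every criterion requires the candidate
    to be active, so the upstream edge must be an activation; an inhibitor
    of a ULK1 activator, for instance, is dropped.  With
    ``activator_rule_only`` the check is applied literally to ULK1
    activators only, leaving other candidates' incoming edges untouched.

    Unsigned edges are dropped and counted.  The output is a subgraph of
    the input and the operation is idempotent.
    """
    records = validate_records(records)
    cand_map = {c.protein: c for c in candidates}
    report = DiscardReport()
    keep_rows = []
    for idx, row in records.iterrows():
        x = row["target"]
        if x not in cand_map or row["source"] == x:
            report.not_incoming += 1
            continue
        if row["sign"] == "unknown":
            report.unsigned += 1
            continue
        c = cand_map[x]
        rule_applies = c.activates_ulk1 if activator_rule_only else True
        if rule_applies and row["sign"] != "activation":
            report.sign_inconsistent += 1
            continue
        keep_rows.append(idx)
    return records.loc[keep_rows].copy(), report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return validate_records(df)


def write_edge_table(records: pd.DataFrame, path) -> None:
    validate_records(records).to_csv(path, sep="\t", index=False)


def write_sif(records: pd.DataFrame, path) -> None:
    """Simple-interaction-format export for graph viewers."""
    with open(path, "w") as fh:
        for _, row in validate_records(records).iterrows():
            fh.write(f"{row['source']}\t{row['sign']}\t{row['target']}\n")
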