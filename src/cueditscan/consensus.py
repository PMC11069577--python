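"""Union and intersection consensus over the two primary predictors.

The consensus models are purely set-theoretic: the union model calls a site
if either the rules-based or the random-forest model calls it, and the
intersection model only if both do.  Union therefore bounds recall from
above and intersection bounds precision from above among the four models.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SitePrediction", "combine", "ConsensusError"]

SiteId = tuple[str, int]  # (gene, 1-based c position)


class ConsensusError(ValueError):
    """The two primary models did not cover the same site universe."""


@dataclass(frozen=True)
class SitePrediction:
    """Per-site calls from both primary models and both consensus models."""

    gene: str
    c_pos: int
    rules_score: int | None
    rules_call: bool
    rf_prob: float
    rf_call: bool

    @property
    def union_call(self) -> bool:
        return self.rules_call or self.rf_call

    @property
    def intersection_call(self) -> bool:
        return self.rules_call and self.rf_call

    @property
    def site_id(self) -> SiteId:
        return (self.gene, self.c_pos)


def combine(rules_calls: dict[SiteId, bool], rf_calls: dict[SiteId, bool],
            mode: str) -> set[SiteId]:
    """Set of positive sites under ``union`` or ``intersection`` consensus.

    Both call maps must cover exactly the same sites; a mismatch raises
    :class:`ConsensusError` listing the missing sites.
    """
    if rules_calls.keys() != rf_calls.keys():
        only_rules = sorted(rules_calls.keys() - rf_calls.keys())
        only_rf = sorted(rf_calls.keys() - rules_calls.keys())
        raise ConsensusError(
            f"site universes differ: {len(only_rules)} sites only in rules "
            f"map (e.g. {only_rules[:3]}), {len(only_rf)} only in rf map "
            f"(e.g. {only_rf[:3]})"
        )
    rules_pos = {s for s, call in rules_calls.items() if call}
    rf_pos = {s for s, call in rf_calls.items() if call}
    if mode == "union":
        return rules_pos | rf_pos
    if mode == "intersection":
        return rules_pos & rf_pos
    raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
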