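"""Discordance screen: probes regulated in opposite directions by two stresses.

For each probe shared between two signatures the discordance statistic is

    d[g] = pi_a[g] * pi_b[g]   if sign(beta_a[g]) != sign(beta_b[g]),
    d[g] = 0                   otherwise,

i.e. the joint probability (under independence) that the probe responds to
both treatments, counted only when the estimated effects point in opposite
directions.  Probes with a zero effect in either signature have no
direction to oppose and are treated as concordant.  Selection keeps the
probes inside the top ``top_frac`` of the ranking with d > 0; probes tied
at the quantile boundary are all included so the result cannot depend on
input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .signature import SignatureModel

__all__ = ["DiscordanceResult", "select_discordant"]


@dataclass
class DiscordanceResult:
    """Ranked discordance table and the selected opposite-direction set."""

    table: pd.DataFrame      # per shared probe: d, sign_a, sign_b, selected
    selected: pd.Index       # ranked by descending d
    top_frac: float
    label_a: str = ""
    label_b: str = ""

    @property
    def up_in_a(self) -> pd.Index:
        t = self.table.loc[self.selected]
        return t.index[t["sign_a"] > 0]

    @property
    def up_in_b(self) -> pd.Index:
        t = self.table.loc[self.selected]
        return t.index[t["sign_b"] > 0]


def select_discordant(
    model_a: SignatureModel,
    model_b: SignatureModel,
    top_frac: float = 0.01,
) -> DiscordanceResult:
    """Select probes with significant but opposite effects in two signatures.

    ``top_frac`` is the fraction of shared probes retained (e.g. 0.01 keeps
    the top 1% by joint probability of differential expression).
    """
    if not 0 < top_frac <= 1:
        raise ValidationError(f"top_frac must be in (0, 1], got {top_frac}")
    shared = model_a.table.index.intersection(model_b.table.index)
    if len(shared) == 0:
        raise ValidationError("signatures share no probes")
    ta = model_a.table.loc[shared]
    tb = model_b.table.loc[shared]
    sign_a = np.sign(ta["beta"].to_numpy())
    sign_b = np.sign(tb["beta"].to_numpy())
    opposite = sign_a * sign_b == -1  # beta == 0 in either -> concordant
    d = ta["pi"].to_numpy() * tb["pi"].to_numpy() * opposite

    table = pd.DataFrame(
        {"d": d, "sign_a": sign_a.astype(int), "sign_b": sign_b.astype(int)},
        index=shared,
    )
    ranked = sorted(range(len(shared)), key=lambda i: (-d[i], str(shared[i])))
    k = math.ceil(top_frac * len(shared))
    d_sorted = d[ranked]
    cutoff = d_sorted[k - 1]
    if cutoff > 0:
        selected_mask = d >= cutoff  # boundary ties all included
    else:
        selected_mask = d > 0
    selected = pd.Index(
        [shared[i] for i in ranked if selected_mask[i]], name=shared.name
    )
    table["selected"] = selected_mask
    return DiscordanceResult(
        table=table,
        selected=selected,
        top_frac=top_frac,
        label_a=model_a.label,
        label_b=model_b.label,
    )
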