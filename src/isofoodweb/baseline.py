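"""Per-site algae δ15N baselines and baseline correction of consumer δ15N.

Raw consumer δ15N is not comparable across sites because the δ15N of the base
of the food web varies spatially; subtracting the site's primary-producer
(algae) mean puts all consumers on a common scale.  δ13C is left uncorrected
(no lipid correction was required; C:N < 3.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from isofoodweb.data_model import BaselineRecord

__all__ = ["SiteBaseline", "MissingBaselineError", "site_baselines", "adjust_d15n"]


class MissingBaselineError(KeyError):
    """A consumer site has no algae baseline records."""


@dataclass
class SiteBaseline:
    site_id: str
    d15n_baseline: float
    n_algae: int

    def __post_init__(self) -> None:
        if self.n_algae < 1:
            raise ValueError("n_algae must be >= 1")


def site_baselines(algae: Iterable[BaselineRecord]) -> dict[str, SiteBaseline]:
    """Arithmetic mean algae δ15N per site (pooled across visits)."""
    sums: dict[str, list[float]] = {}
    for rec in algae:
        sums.setdefault(rec.site_id, []).append(rec.d15n_permil)
    return {
        site: SiteBaseline(site, sum(v) / len(v), len(v)) for site, v in sums.items()
    }


def adjust_d15n(
    consumers: pd.DataFrame, baselines: dict[str, SiteBaseline]
) -> pd.DataFrame:
    """Add ``d15n_adjusted = d15n_permil − site baseline``; raw columns kept.

    Raises :class:`MissingBaselineError` listing every consumer site that has
    no baseline.
    """
    missing = sorted(set(consumers["site_id"]) - set(baselines))
    if missing:
        raise MissingBaselineError(
            f"no algae baseline for site(s): {', '.join(missing)}"
        )
    out = consumers.copy()
    out["d15n_adjusted"] = out["d15n_permil"] - out["site_id"].map(
        {s: b.d15n_baseline for s, b in baselines.items()}
    )
    return out
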