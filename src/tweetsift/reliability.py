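"""Krippendorff's alpha for nominal data (intercoder reliability).

alpha = 1 - Do/De, with observed and expected disagreement computed from
the coincidence matrix. For nominal data the distance between two
categories is 0 when equal and 1 otherwise, so

    Do = (1/n) * sum_{c != k} o_ck
    De = sum_{c != k} n_c * n_k / (n * (n - 1))

where ``o_ck`` counts coincidences of categories c and k within units
(each unit with m codings contributes each ordered pair with weight
1/(m-1)), ``n_c`` are the matrix marginals and ``n`` their total. Units
with fewer than two codings carry no pairable information and are
excluded. When every coding falls in one category, De = 0 and alpha is
undefined; this is reported as a flagged result, not an exception.

Per-category (binary) alphas collapse the data to {category, not-category}
and rerun the same routine — the style in which agreement is usually
reported for multi-category codebooks.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, NamedTuple

__all__ = ["ReliabilityTable", "AlphaResult", "krippendorff_alpha", "per_category_alphas"]


@dataclass(frozen=True)
class ReliabilityTable:
    """Codings: (coder, unit) -> nominal category; missing cells simply absent."""

    values: dict[tuple[str, str], Hashable]

    def __post_init__(self) -> None:
        if len(self.coders) < 2:
            raise ValueError("reliability table needs >=2 coders")
        if not any(len(v) >= 2 for v in self._by_unit().values()):
            raise ValueError("no unit carries >=2 codings")

    @property
    def coders(self) -> list[str]:
        return sorted({c for c, _ in self.values})

    @property
    def units(self) -> list[str]:
        return sorted({u for _, u in self.values})

    def _by_unit(self) -> dict[str, list[Hashable]]:
        out: dict[str, list[Hashable]] = {}
        for (coder, unit), v in sorted(self.values.items()):
            out.setdefault(unit, []).append(v)
        return out

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, Hashable]]) -> "ReliabilityTable":
        """Build from (unit, coder, value) triples."""
        return cls({(coder, unit): v for unit, coder, v in records})

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReliabilityTable":
        """CSV with header ``unit,coder,value``."""
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            return cls.from_records(
                (row["unit"], row["coder"], row["value"]) for row in reader
            )


class AlphaResult(NamedTuple):
    alpha: float | None
    defined: bool
    Do: float
    De: float
    n_pairable: int  # codings in units with >=2 codings


def krippendorff_alpha(table: ReliabilityTable) -> AlphaResult:
    """Nominal-metric Krippendorff's alpha from the coincidence matrix."""
    coincidence: Counter[tuple[Hashable, Hashable]] = Counter()
    n_pairable = 0
    for unit_values in table._by_unit().values():
        m = len(unit_values)
        if m < 2:
            continue
        n_pairable += m
        w = 1.0 / (m - 1)
        for i, vi in enumerate(unit_values):
            for j, vj in enumerate(unit_values):
                if i != j:
                    coincidence[(vi, vj)] += w
    n = sum(coincidence.values())  # == n_pairable
    marginals: Counter[Hashable] = Counter()
    for (c, _k), v in coincidence.items():
        marginals[c] += v
    Do = sum(v for (c, k), v in coincidence.items() if c != k) / n
    De_num = sum(
        marginals[c] * marginals[k]
        for c in marginals
        for k in marginals
        if c != k
    )
    De = De_num / (n * (n - 1))
    if De == 0.0:
        return AlphaResult(None, False, Do, De, n_pairable)
    return AlphaResult(1.0 - Do / De, True, Do, De, n_pairable)


def per_category_alphas(table: ReliabilityTable) -> dict[Hashable, AlphaResult]:
    """Binary alpha per category: collapse codings to {category, other}."""
    categories = sorted({v for v in table.values.values()}, key=str)
    out: dict[Hashable, AlphaResult] = {}
    for cat in categories:
        collapsed = ReliabilityTable(
            {key: (v == cat) for key, v in table.values.items()}
        )
        out[cat] = krippendorff_alpha(collapsed)
    return out
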