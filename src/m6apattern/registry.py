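"""Curated m6A-regulator registry and variant summarization."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import CnvCalls, MutationTable, NON_SILENT_CLASSES

__all__ = [
    "RegulatorRegistry",
    "load_regulator_registry",
    "mutation_frequency",
    "cnv_frequency",
]

# symbol -> functional role; 7 writers, 13 readers, 2 erasers
_REGULATORS: tuple[tuple[str, str], ...] = (
    ("METTL3", "writer"),
    ("METTL16", "writer"),
    ("WTAP", "writer"),
    ("VIRMA", "writer"),
    ("RBM15", "writer"),
    ("RBM15B", "writer"),
    ("ZC3H13", "writer"),
    ("YTHDC1", "reader"),
    ("YTHDC2", "reader"),
    ("YTHDF1", "reader"),
    ("YTHDF2", "reader"),
    ("YTHDF3", "reader"),
    ("HNRNPA2B1", "reader"),
    ("HNRNPC", "reader"),
    ("IGF2BP2", "reader"),
    ("LRPPRC", "reader"),
    ("RBMX", "reader"),
    ("EIF3A", "reader"),
    ("G3BP1", "reader"),
    ("FXR1", "reader"),
    ("ALKBH5", "eraser"),
    ("FTO", "eraser"),
)

ROLES = ("writer", "reader", "eraser")


@dataclass(frozen=True)
class RegulatorRegistry:
    """The 22-gene writer/reader/eraser panel driving the analysis."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        symbols = [s for s, _ in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate regulator symbols")
        bad = {r for _, r in self.entries} - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.entries]

    def role(self, symbol: str) -> str:
        for s, r in self.entries:
            if s == symbol:
                return r
        raise KeyError(symbol)

    def by_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [s for s, r in self.entries if r == role]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["symbol", "role"]).set_index("symbol")


def load_regulator_registry() -> RegulatorRegistry:
    """Return the bundled 22-entry regulator registry."""
    return RegulatorRegistry(_REGULATORS)


def mutation_frequency(
    muts: MutationTable,
    genes: Sequence[str],
    n_samples: int,
    non_silent_classes: Iterable[str] = NON_SILENT_CLASSES,
) -> tuple[int, float]:
    """Count samples carrying >= 1 non-silent variant in any listed gene.

    Returns ``(count, count / n_samples)``. A sample mutated in several
    listed genes is counted once.
    """
    if not len(genes):
        raise ValueError("gene list is empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ns = muts.non_silent(non_silent_classes)
    hit = ns[ns["gene_symbol"].isin(set(genes))]
    count = hit["sample_id"].nunique()
    return count, count / n_samples


def cnv_frequency(cnv: CnvCalls, genes: Sequence[str]) -> pd.DataFrame:
    """Per-gene fraction of samples with copy-number gain / loss.

    Returns a DataFrame indexed by gene with columns ``gain_freq`` and
    ``loss_freq``, both in [0, 1].
    """
    missing = [g for g in genes if g not in cnv.calls.index]
    if missing:
        raise KeyError(f"genes without CNV calls: {missing}")
    sub = cnv.calls.loc[list(genes)]
    return pd.DataFrame(
        {
            "gain_freq": (sub == 1).mean(axis=1),
            "loss_freq": (sub == -1).mean(axis=1),
        }
    )
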