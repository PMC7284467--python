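"""Gene-set over-representation analysis (ORA) on significant markers.

Given a GMT gene-set collection restricted to a background universe, each
pathway is tested with the upper-tail hypergeometric probability
``P(X >= k)`` of drawing ``k`` pathway members when ``n`` markers are
selected from a background of ``N`` containing ``K`` pathway members.  The
enrichment ratio is ``(k/n) / (K/N)``.  Q-values are BH-adjusted across the
tested pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .association_scan import bh_fdr
from .errors import ConfigurationError, InputError

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "filter_pathways",
    "ora_test",
    "annotate_members",
]

RESULT_COLUMNS = (
    "pathway", "set_size", "n_selected", "overlap",
    "enrichment_ratio", "p", "q", "matched_members",
)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named member sets plus the background identifier universe."""

    sets: dict[str, frozenset]
    background: frozenset

    def __post_init__(self):
        stray = {m for s in self.sets.values() for m in s} - self.background
        if stray:
            raise ConfigurationError(
                f"set members outside background: {sorted(stray)[:5]}..."
                if len(stray) > 5 else
                f"set members outside background: {sorted(stray)}"
            )

    def restricted(self, universe) -> "GeneSetCollection":
        """Adopt an explicit universe as background, restricting all sets."""
        uni = frozenset(universe)
        return GeneSetCollection(
            sets={n: s & uni for n, s in self.sets.items()},
            background=uni,
        )

    def sizes(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.sets.items()}


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a GMT file (name, description, members per tab-separated line).

    The declared background defaults to the union of all set members; an
    explicit ``universe`` (iterable of ids) overrides it and restricts every
    set.  Duplicate members within a set are deduplicated with a warning.
    """
    path = Path(path)
    sets: dict[str, frozenset] = {}
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise InputError(f"empty GMT file: {path}")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        name, _description, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
        unique = frozenset(members)
        if len(unique) < len(members):
            warnings.warn(f"{path}:{lineno}: duplicate members in {name!r} "
                          "deduplicated", stacklevel=2)
        sets[name] = unique
    background = frozenset().union(*sets.values()) if sets else frozenset()
    collection = GeneSetCollection(sets=sets, background=background)
    if universe is not None:
        collection = collection.restricted(universe)
    return collection


def filter_pathways(collection: GeneSetCollection, min_size: int = 5,
                    max_size: int = 2000) -> GeneSetCollection:
    """Retain sets whose background-restricted size lies in [min_size, max_size]."""
    if min_size > max_size:
        raise ConfigurationError("min_size must be <= max_size")
    kept = {n: s for n, s in collection.sets.items()
            if min_size <= len(s) <= max_size}
    return GeneSetCollection(sets=kept, background=collection.background)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)):
        raise InputError(f"impossible overlap k={k} for K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_test(selected, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in every pathway.

    Selected ids missing from the background are dropped with a warning and
    reported via the frame's ``.attrs`` (``n_mapped`` / ``unmapped``).
    Results are sorted by p-value.
    """
    selected = set(selected)
    unmapped = sorted(selected - collection.background)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} selected id(s) not in background, dropped",
            stacklevel=2,
        )
    mapped = selected & collection.background
    N = len(collection.background)
    n = len(mapped)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        matched = sorted(mapped & members)
        k = len(matched)
        if n == 0:
            continue
        expected = K / N
        ratio = (k / n) / expected if expected > 0 else float("nan")
        rows.append({
            "pathway": name, "set_size": K, "n_selected": n, "overlap": k,
            "enrichment_ratio": ratio,
            "p": hypergeom_upper_tail(N, K, n, k),
            "matched_members": ";".join(matched),
        })
    out = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "q"])
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    out = out[list(RESULT_COLUMNS)]
    out.attrs["n_mapped"] = n
    out.attrs["unmapped"] = unmapped
    return out


def annotate_members(selected, collection: GeneSetCollection) -> pd.DataFrame:
    """Descriptive mapping of selected ids to set names, with no test.

    Mirrors the metabolite treatment: one row per (id, pathway) membership.
    """
    selected = set(selected)
    rows = [
        {"marker_id": m, "pathway": name}
        for name, members in collection.sets.items()
        for m in sorted(selected & members)
    ]
    return (pd.DataFrame(rows, columns=["marker_id", "pathway"])
            .sort_values(["marker_id", "pathway"], kind="stable")
            .reset_index(drop=True))
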