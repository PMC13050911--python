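"""Compact letter display for post-hoc pairwise comparisons."""

from __future__ import annotations

import string


def compact_letters(groups, pair_p: dict, means: dict, alpha: float = 0.05) -> dict:
    """Assign significance letters so two groups share a letter iff their
    pairwise p-value is >= alpha (insert-and-absorb algorithm).

    ``pair_p`` maps frozenset({a, b}) -> p.  Letters are ordered by
    descending group mean; ties broken by group name.
    """
    groups = list(groups)
    letters = [set(groups)]
    for a in groups:
        for b in groups:
            if a >= b:
                continue
            p = pair_p.get(frozenset((a, b)), 1.0)
            if p < alpha:
                new = []
                for s in letters:
                    if a in s and b in s:
                        new.append(s - {a})
                        new.append(s - {b})
                    else:
                        new.append(s)
                # absorb sets contained in another
                letters = [
                    s for i, s in enumerate(new)
                    if s and not any(s < t or (s == t and i > j)
                                     for j, t in enumerate(new) if i != j)
                ]
    # order letter sets by the best (highest-mean) member
    order = sorted(groups, key=lambda g: (-means.get(g, 0.0), g))
    rank = {g: i for i, g in enumerate(order)}
    letters.sort(key=lambda s: min(rank[g] for g in s))
    out = {g: "" for g in groups}
    for ch, s in zip(string.ascii_lowercase, letters):
        for g in sorted(s, key=lambda g: rank[g]):
            out[g] += ch
    return out
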