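"""Expansion of a query motif into residue-type variants.

A search can tolerate mutated target motifs. Four strategies control which
substitutions are considered at each motif position:

* ``strict`` — no substitutions; only the exact residue types match.
* ``pse`` (position-specific exchanges) — the user lists, per position, the
  replacement residues to allow.
* ``relaxed`` — each position may mutate within its physico-chemical group:
  nonpolar (G, A, V, L, I), polar (S, T, P, N, Q), sulfur-containing (M, C),
  positively charged (K, R, H), negatively charged (D, E), and aromatic
  (F, Y, W).
* ``fully_relaxed`` — each position may mutate into any of the 19 other
  amino acids.

The number of simultaneous mutations in a variant is bounded by
``max_mutations``; variant expansion enumerates every allowed assignment up
to that bound, including the unmutated original.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .geometry import STANDARD_AA

PHYSICOCHEMICAL_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("GAVLI"),   # nonpolar
    frozenset("STPNQ"),   # polar
    frozenset("MC"),      # sulfur-containing
    frozenset("KRH"),     # positively charged
    frozenset("DE"),      # negatively charged
    frozenset("FYW"),     # aromatic
)

STRATEGIES = ("strict", "pse", "relaxed", "fully_relaxed")


class PolicyError(ValueError):
    """Invalid substitution-policy configuration."""


@dataclass(frozen=True)
class SubstitutionPolicy:
    """Per-position allowed replacement sets plus a mutation budget."""

    strategy: str
    replacements: dict[str, frozenset[str]]
    max_mutations: int

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise PolicyError(f"unknown strategy {self.strategy!r}")
        if self.max_mutations < 0:
            raise PolicyError("max_mutations must be >= 0")


@dataclass(frozen=True)
class MotifVariant:
    """One residue-type assignment over the query positions."""

    assignment: tuple[tuple[str, str], ...]  # sorted (position, aa) pairs
    mutation_count: int

    @property
    def types(self) -> dict[str, str]:
        return dict(self.assignment)


def _group_of(aa: str) -> frozenset[str]:
    for group in PHYSICOCHEMICAL_GROUPS:
        if aa in group:
            return group
    raise PolicyError(f"amino acid {aa!r} belongs to no group")


def make_policy(
    strategy: str,
    query_types: dict[str, str],
    max_mutations: int | None = None,
    pse_map: dict[str, str] | None = None,
) -> SubstitutionPolicy:
    """Build the substitution policy for a query.

    ``pse_map`` maps a position to a string of allowed replacement letters
    and is required (non-empty) for the ``pse`` strategy. ``max_mutations``
    defaults to 0 for ``strict`` and 1 for every mutation-permitting
    strategy.
    """
    _validate_types(query_types)
    if max_mutations is None:
        max_mutations = 0 if strategy == "strict" else 1
    if strategy == "strict":
        repl = {pos: frozenset() for pos in query_types}
    elif strategy == "pse":
        if not pse_map:
            raise PolicyError("pse strategy requires per-position substitutions")
        unknown = set(pse_map) - set(query_types)
        if unknown:
            raise PolicyError(f"substitutions for unknown positions: {sorted(unknown)}")
        repl = {pos: frozenset() for pos in query_types}
        for pos, letters in pse_map.items():
            letters_set = frozenset(letters.upper())
            bad = letters_set - STANDARD_AA
            if bad:
                raise PolicyError(f"invalid amino-acid letters {sorted(bad)} at {pos}")
            if query_types[pos] in letters_set:
                raise PolicyError(
                    f"replacement set at {pos} must exclude the original residue"
                )
            repl[pos] = letters_set
    elif strategy == "relaxed":
        repl = {
            pos: _group_of(aa) - {aa} for pos, aa in query_types.items()
        }
    else:  # fully_relaxed
        repl = {pos: STANDARD_AA - {aa} for pos, aa in query_types.items()}
    return SubstitutionPolicy(strategy=strategy, replacements=repl,
                              max_mutations=max_mutations)


def _validate_types(query_types: dict[str, str]) -> None:
    bad = {aa for aa in query_types.values() if aa not in STANDARD_AA}
    if bad:
        raise PolicyError(f"invalid amino-acid letters: {sorted(bad)}")


def expand_variants(
    query_types: dict[str, str], policy: SubstitutionPolicy
) -> list[MotifVariant]:
    """Enumerate every motif variant allowed by *policy*.

    Returns the unmutated assignment plus every assignment in which at most
    ``max_mutations`` positions are substituted, each substitution drawn
    from that position's replacement set. The list is duplicate-free and
    deterministically ordered: ascending mutation count, then
    lexicographically by the (position, residue) assignment.
    """
    _validate_types(query_types)
    positions = sorted(query_types)
    variants: list[MotifVariant] = []
    for k in range(min(policy.max_mutations, len(positions)) + 1):
        for mutated in itertools.combinations(positions, k):
            pools = [
                sorted(policy.replacements.get(pos, frozenset()))
                for pos in mutated
            ]
            if any(not p for p in pools):
                continue
            for combo in itertools.product(*pools):
                types = dict(query_types)
                for pos, aa in zip(mutated, combo):
                    types[pos] = aa
                variants.append(
                    MotifVariant(
                        assignment=tuple(sorted(types.items())),
                        mutation_count=k,
                    )
                )
    seen: set[tuple] = set()
    unique: list[MotifVariant] = []
    for v in sorted(variants, key=lambda v: (v.mutation_count, v.assignment)):
        if v.assignment not in seen:
            seen.add(v.assignment)
            unique.append(v)
    return unique
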