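"""A minimal slice of the PSI-MI controlled vocabulary.

Only the terms the filtering stages reason about are included: the
interaction-type branch (association / physical association / direct
interaction / colocalization / proximity) and the mutation feature branch
with its effect-direction children.  Both tables are plain dicts so a caller
with a fuller CV export can substitute their own.

The mutation branch drives two things: the "Mutation" corpus filter
(membership of a feature type in the closure) and the per-participant effect
classification (increasing / decreasing / disrupting / causing with no
stated direction).
"""

from __future__ import annotations

from .errors import ConfigurationError

# id -> (label, parent id or None)
INTERACTION_TYPES: dict[str, tuple[str, str | None]] = {
    "MI:0190": ("interaction type", None),
    "MI:0914": ("association", "MI:0190"),
    "MI:0915": ("physical association", "MI:0914"),
    "MI:0407": ("direct interaction", "MI:0915"),
    "MI:0403": ("colocalization", "MI:0190"),
    "MI:2364": ("proximity", "MI:0190"),
}

# Effect categories used by MutationEffect.
INCREASING = "increasing"
DECREASING = "decreasing"
DISRUPTING = "disrupting"
CAUSING = "causing"  # mutation affects the interaction, direction unstated
UNKNOWN = "unknown"

# id -> (label, effect category). Parent term first; children carry the
# direction of the effect on the interaction.
MUTATION_TERMS: dict[str, tuple[str, str]] = {
    "MI:0118": ("mutation", CAUSING),
    "MI:0119": ("mutation decreasing interaction", DECREASING),
    "MI:1130": ("mutation decreasing interaction rate", DECREASING),
    "MI:1133": ("mutation decreasing interaction strength", DECREASING),
    "MI:0382": ("mutation increasing interaction", INCREASING),
    "MI:1131": ("mutation increasing interaction rate", INCREASING),
    "MI:1132": ("mutation increasing interaction strength", INCREASING),
    "MI:0573": ("mutation disrupting interaction", DISRUPTING),
    "MI:1128": ("mutation disrupting interaction rate", DISRUPTING),
    "MI:1129": ("mutation disrupting interaction strength", DISRUPTING),
    "MI:2226": ("mutation with no effect", UNKNOWN),
    "MI:2227": ("mutation causing an interaction", CAUSING),
}

DEFAULT_MUTATION_CLOSURE: frozenset[str] = frozenset(MUTATION_TERMS)

_LABEL_TO_MUTATION_ID = {label: mid for mid, (label, _) in MUTATION_TERMS.items()}


def descendants(root_ids: set[str], table: dict[str, tuple[str, str | None]]) -> set[str]:
    """Return ``root_ids`` plus every term reachable below them in ``table``."""
    closure = set(root_ids)
    changed = True
    while changed:
        changed = False
        for term_id, (_, parent) in table.items():
            if parent in closure and term_id not in closure:
                closure.add(term_id)
                changed = True
    return closure


def validate_mutation_closure(term_ids: set[str]) -> None:
    unknown = sorted(t for t in term_ids if t not in MUTATION_TERMS)
    if unknown:
        raise ConfigurationError(
            f"unknown CV id(s) in mutation-term closure: {', '.join(unknown)}"
        )


def mutation_id_for_label(label: str) -> str | None:
    return _LABEL_TO_MUTATION_ID.get(label.strip().lower())


def effect_category(term_id: str | None, label: str | None) -> str:
    """Classify a mutation feature type into an effect category.

    The CV id is authoritative; the label is a fallback for records whose
    feature column carries only the term name (common in curated exports).
    """
    if term_id and term_id in MUTATION_TERMS:
        return MUTATION_TERMS[term_id][1]
    if label:
        low = label.strip().lower()
        if low in _LABEL_TO_MUTATION_ID:
            return MUTATION_TERMS[_LABEL_TO_MUTATION_ID[low]][1]
    return UNKNOWN
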