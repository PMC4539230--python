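"""Scenario scripts and their rendering.

The three scenario scripts (positive health outcome, negative outcome, and
negative outcome with an expression of regret) ship as text fixtures.  They
share a common scaffold and differ only in four manipulated spans: the
friend's expressed reaction, the quoted statement, the HIV test result, and
the closing sentence.  Rendering substitutes the participant's gender
(friend is described as the same gender, with matching pronouns) and age.
"""

from __future__ import annotations

from importlib import resources

__all__ = ["TEMPLATE_IDS", "render_scenario", "template_text", "manipulated_spans"]

TEMPLATE_IDS = ("positive", "negative", "negative_regret")

# Exact manipulated spans, used to verify the scripts are identical up to
# the manipulation.
MANIPULATED_SPANS: dict[str, tuple[str, ...]] = {
    "positive": (
        "expressed extreme excitement",
        '"I had such a good time and my partner was very attractive. '
        'I can\'t wait to see them again!"',
        "tested negative for",
        "Taylor is extremely happy and called you jumping for joy.",
    ),
    "negative": (
        "expressed extreme excitement",
        '"I had a great time and my partner was very attractive. '
        'I\'m excited to see them again!"',
        "tested positive for",
        "Taylor is profoundly devastated, afraid {his_her} whole life is over, "
        "and crying uncontrollably.",
    ),
    "negative_regret": (
        "expressed extreme regret",
        '"I knew I should have used protection that night. What was I thinking?!"',
        "tested positive for",
        "Taylor is profoundly devastated, afraid {his_her} whole life is over, "
        "and wishes {s_he} never made the mistake.",
    ),
}

_PRONOUNS = {
    "male": {"s_he": "he", "S_he": "He", "his_her": "his"},
    "female": {"s_he": "she", "S_he": "She", "his_her": "her"},
}


def template_text(template_id: str) -> str:
    """Raw template with gender/age placeholders."""
    if template_id not in TEMPLATE_IDS:
        raise ValueError(f"unknown scenario template {template_id!r}")
    ref = resources.files("sexdisc") / "templates" / f"{template_id}.txt"
    return ref.read_text(encoding="utf-8").strip()


def render_scenario(template_id: str, gender: str, age: int) -> str:
    """Substitute the participant's gender (and pronouns) and age."""
    if gender not in _PRONOUNS:
        raise ValueError(f"gender must be 'male' or 'female', got {gender!r}")
    subs = dict(_PRONOUNS[gender], gender=gender, age=str(age))
    return template_text(template_id).format(**subs)


def manipulated_spans(template_id: str, gender: str = "female") -> tuple[str, ...]:
    """The rendered manipulated spans of one template."""
    if template_id not in TEMPLATE_IDS:
        raise ValueError(f"unknown scenario template {template_id!r}")
    subs = dict(_PRONOUNS[gender], gender=gender)
    return tuple(s.format(**subs) for s in MANIPULATED_SPANS[template_id])
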