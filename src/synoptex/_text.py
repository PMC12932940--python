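"""Text normalization shared by matching, parsing and scoring.

"Exact match" throughout the package means equality of *normalized* forms:
trimmed, internal whitespace collapsed, casefolded, and all Unicode dash
variants unified to the ASCII hyphen. Numeric display templates (e.g.
"Exact distance: — mm") additionally drop their placeholder dash before
matching, so the template matches report text such as "Exact distance: mm".
"""
from __future__ import annotations

import re

#: Sentinel value meaning "the backend explicitly declined to extract".
ABSTAIN = "ABSTAIN"

#: Dash variants unified to "-" (em, en, figure, hyphen, non-breaking, minus).
_DASHES = "—–‒‐‑−"

_WS = re.compile(r"\s+")


def normalize(text: str) -> str:
    """Canonical comparison form of a value or snippet."""
    for dash in _DASHES:
        text = text.replace(dash, "-")
    return _WS.sub(" ", text.casefold()).strip()


def template_match_form(template: str) -> str:
    """Matchable form of a numeric display template: placeholder removed.

    "Exact distance: — mm" -> "exact distance: mm"
    """
    for dash in _DASHES + "-":
        template = template.replace(dash, " ")
    return _WS.sub(" ", template.casefold()).strip()
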