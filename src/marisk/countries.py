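"""Country name <-> ISO 3166-1 alpha-3 registry.

Maritime-trade tables in the wild identify countries by English short
name; everything downstream of the readers works with alpha-3 codes.
The registry covers the coastal African countries plus the South Asian
and Arabian-Peninsula countries relevant to *Anopheles stephensi*
source populations.  Synthetic country codes (any three ASCII letters)
are accepted as-is, so generated scenarios need no registry entries.
"""

from __future__ import annotations

import re

__all__ = ["NAME_TO_CODE", "UnknownCountryError", "canonical_code"]


class UnknownCountryError(ValueError):
    """A country name that is not in the registry (never silently dropped)."""


NAME_TO_CODE: dict[str, str] = {
    # Coastal Africa
    "algeria": "DZA",
    "angola": "AGO",
    "benin": "BEN",
    "cameroon": "CMR",
    "cabo verde": "CPV",
    "cape verde": "CPV",
    "comoros": "COM",
    "congo": "COG",
    "republic of the congo": "COG",
    "democratic republic of the congo": "COD",
    "dr congo": "COD",
    "cote d'ivoire": "CIV",
    "ivory coast": "CIV",
    "djibouti": "DJI",
    "egypt": "EGY",
    "equatorial guinea": "GNQ",
    "eritrea": "ERI",
    "gabon": "GAB",
    "gambia": "GMB",
    "the gambia": "GMB",
    "ghana": "GHA",
    "guinea": "GIN",
    "guinea-bissau": "GNB",
    "kenya": "KEN",
    "liberia": "LBR",
    "libya": "LBY",
    "madagascar": "MDG",
    "mauritania": "MRT",
    "mauritius": "MUS",
    "morocco": "MAR",
    "mozambique": "MOZ",
    "namibia": "NAM",
    "nigeria": "NGA",
    "sao tome and principe": "STP",
    "senegal": "SEN",
    "seychelles": "SYC",
    "sierra leone": "SLE",
    "somalia": "SOM",
    "south africa": "ZAF",
    "sudan": "SDN",
    "tanzania": "TZA",
    "united republic of tanzania": "TZA",
    "togo": "TGO",
    "tunisia": "TUN",
    # Landlocked but frequently referenced
    "ethiopia": "ETH",
    # Source-population region
    "india": "IND",
    "pakistan": "PAK",
    "saudi arabia": "SAU",
    "united arab emirates": "ARE",
    "uae": "ARE",
    "iran": "IRN",
    "iraq": "IRQ",
    "thailand": "THA",
    "myanmar": "MMR",
}

_CODE_RE = re.compile(r"^[A-Za-z]{3}$")


def _normalize_name(name: str) -> str:
    name = name.strip().lower().replace("’", "'")
    return re.sub(r"\s+", " ", name)


def canonical_code(token: str) -> str:
    """Map a country token (alpha-3 code or English name) to an alpha-3 code.

    Three-letter tokens are treated as codes and uppercased; anything else
    is looked up in the name registry.  Unknown names raise
    :class:`UnknownCountryError` — a silent drop would corrupt rankings.
    """
    token = str(token).strip()
    if not token:
        raise UnknownCountryError("empty country token")
    if _CODE_RE.match(token):
        return token.upper()
    key = _normalize_name(token)
    try:
        return NAME_TO_CODE[key]
    except KeyError:
        raise UnknownCountryError(f"unknown country name: {token!r}") from None
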