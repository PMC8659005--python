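"""WURCS-keyed GlyTouCan accession lookup.

The GlyCosmos portal exposes a web API that takes a WURCS string and
returns the matching GlyTouCan accession; entry pages live under
``https://glycosmos.org/glycans/show/<accession>``. The client here is a
thin, endpoint-configurable wrapper: transport is injectable (tests run
fully offline with a stub), HTTP failures are reported as
``status="error"`` results rather than exceptions, and syntactically
invalid WURCS is rejected before any network activity.
"""

from __future__ import annotations

import json
import re
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from typing import Callable, Optional

from .errors import ValidationError

#: GlyTouCan accessions look like "G12345XY" (8 alphanumerics starting
#: with G). The check is advisory only — unexpected shapes are accepted.
ACCESSION_RE = re.compile(r"^G[0-9A-Z]{7}$")

_WURCS_SHAPE_RE = re.compile(
    r"^WURCS=2\.0/\d+,\d+,\d+/(?:\[[^\[\]]+\])+/[0-9-]+/"
)

#: transport(url, timeout) -> (http status code, response body text)
Transport = Callable[[str, float], tuple[int, str]]


@dataclass(frozen=True)
class EndpointConfig:
    """Where to search and how to build result links."""

    search_endpoint: str = (
        "https://api.glycosmos.org/glytoucan/sparql/wurcs2gtcids"
    )
    entry_base: str = "https://glycosmos.org/glycans/show/"
    image_base: str = "https://image.glycosmos.org/snfg/png/"
    timeout: float = 30.0


@dataclass(frozen=True)
class SearchResult:
    query_wurcs: str
    status: str                     # found | not_registered | error
    accession: Optional[str] = None
    entry_url: Optional[str] = None
    image_url: Optional[str] = None
    detail: str = ""


def _default_transport(url: str, timeout: float) -> tuple[int, str]:
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        return resp.status, resp.read().decode("utf-8", "replace")


def check_wurcs_syntax(wurcs: str) -> None:
    """Light structural check; raises ValidationError when the string is
    not shaped like a WURCS 2.0 sequence."""
    if not _WURCS_SHAPE_RE.match(wurcs.strip()):
        raise ValidationError(f"not a syntactically valid WURCS: {wurcs!r}")


def _extract_accession(payload) -> Optional[str]:
    """Tolerant accession extractor: the response schema is not fixed, so
    look for conventional keys first, then any accession-shaped string."""
    if isinstance(payload, dict):
        for key in ("id", "accession", "accessionNumber", "GlyTouCan"):
            value = payload.get(key)
            if isinstance(value, str) and value:
                return value
        for value in payload.values():
            found = _extract_accession(value)
            if found:
                return found
    elif isinstance(payload, list):
        for item in payload:
            found = _extract_accession(item)
            if found:
                return found
    elif isinstance(payload, str) and ACCESSION_RE.match(payload):
        return payload
    return None


def build_entry_links(accession: str,
                      config: EndpointConfig = EndpointConfig()
                      ) -> tuple[str, str]:
    """(entry page URL, image URL) for an accession — pure string work."""
    if not accession:
        raise ValidationError("empty accession")
    return config.entry_base + accession, config.image_base + accession


def search_glytoucan(wurcs: str,
                     config: EndpointConfig = EndpointConfig(),
                     transport: Optional[Transport] = None) -> SearchResult:
    """Look a WURCS string up in GlyTouCan via the configured endpoint.

    Never raises for transport-level failures: timeouts, connection
    errors and non-2xx responses all yield ``status="error"`` with a
    diagnostic in ``detail``.
    """
    check_wurcs_syntax(wurcs)  # before any network activity
    transport = transport or _default_transport
    url = (
        config.search_endpoint
        + "?"
        + urllib.parse.urlencode({"wurcs": wurcs})
    )
    try:
        status_code, body = transport(url, config.timeout)
    except Exception as exc:  # noqa: BLE001 - fail soft by contract
        return SearchResult(
            query_wurcs=wurcs, status="error",
            detail=f"transport failure: {exc}",
        )
    if not 200 <= status_code < 300:
        return SearchResult(
            query_wurcs=wurcs, status="error",
            detail=f"HTTP {status_code}",
        )
    try:
        payload = json.loads(body)
    except json.JSONDecodeError as exc:
        return SearchResult(
            query_wurcs=wurcs, status="error",
            detail=f"unparseable response: {exc}",
        )
    accession = _extract_accession(payload)
    if not accession:
        return SearchResult(query_wurcs=wurcs, status="not_registered")
    entry_url, image_url = build_entry_links(accession, config)
    return SearchResult(
        query_wurcs=wurcs, status="found", accession=accession,
        entry_url=entry_url, image_url=image_url,
    )
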