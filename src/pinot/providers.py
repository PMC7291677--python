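"""PPI evidence acquisition from PSICQUIC providers.

Human queries pull MITAB text per seed from each configured provider.
Two modes exist: *live*, issuing PSICQUIC REST ``interactor`` queries
over HTTP, and *offline*, reading per-provider fixture files laid out as
``<offline_root>/<provider>/<seed>.mitab``.  Offline mode is
bit-deterministic and is the only mode exercised by the test suite; live
provider content drifts as databases update, so it cannot anchor tests.

A failing provider never aborts a run: it is marked failed in the
provider-status log and the remaining providers' records are used.
"""

from __future__ import annotations

import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path

import yaml

from .mitab import MalformedLine, RawRecord, parse_mitab, parse_mitab_file

#: The seven default human providers, all primary literature-curating
#: databases reachable over PSICQUIC.
DEFAULT_PROVIDER_NAMES = (
    "bhf-ucl",
    "BioGRID",
    "InnateDB",
    "IntAct",
    "MBInfo",
    "MINT",
    "UniProt",
)

_DEFAULT_ENDPOINTS = {
    "bhf-ucl": "https://www.ebi.ac.uk/Tools/webservices/psicquic/bhf-ucl/webservices/current/search/query/{query}",
    "BioGRID": "https://tyersrest.tyerslab.com:8805/psicquic/webservices/current/search/query/{query}",
    "InnateDB": "https://psicquic.curated.innatedb.com/webservices/current/search/query/{query}",
    "IntAct": "https://www.ebi.ac.uk/Tools/webservices/psicquic/intact/webservices/current/search/query/{query}",
    "MBInfo": "https://www.ebi.ac.uk/Tools/webservices/psicquic/mbinfo/webservices/current/search/query/{query}",
    "MINT": "https://www.ebi.ac.uk/Tools/webservices/psicquic/mint/webservices/current/search/query/{query}",
    "UniProt": "https://www.ebi.ac.uk/Tools/webservices/psicquic/uniprot/webservices/current/search/query/{query}",
}


class NoDataSourceError(RuntimeError):
    """Raised when every configured provider is disabled or failed."""


@dataclass(frozen=True)
class ProviderConfig:
    name: str
    endpoint: str = ""
    enabled: bool = True


@dataclass(frozen=True)
class ProviderStatus:
    name: str
    state: str  # responded | failed | skipped
    records_returned: int = 0

    def __post_init__(self) -> None:
        if self.state != "responded" and self.records_returned != 0:
            raise ValueError("only a responding provider returns records")


def default_providers() -> list[ProviderConfig]:
    """The built-in seven-provider human configuration."""
    return [
        ProviderConfig(name, _DEFAULT_ENDPOINTS.get(name, ""))
        for name in DEFAULT_PROVIDER_NAMES
    ]


def load_providers_config(path: str | Path) -> list[ProviderConfig]:
    """Read a YAML provider list overriding the built-in seven.

    Format: a list of mappings with keys ``name`` and optional
    ``endpoint`` / ``enabled``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError("providers config must be a nonempty list")
    return [
        ProviderConfig(
            entry["name"],
            entry.get("endpoint", _DEFAULT_ENDPOINTS.get(entry["name"], "")),
            bool(entry.get("enabled", True)),
        )
        for entry in raw
    ]


def _fetch_live(
    provider: ProviderConfig, seed: str, timeout: float, retries: int = 1
) -> str:
    query = urllib.parse.quote(f"identifier:{seed}")
    url = provider.endpoint.format(query=query)
    last_err: Exception | None = None
    for _ in range(retries + 1):
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                return resp.read().decode("utf-8", errors="replace")
        except (urllib.error.URLError, OSError, TimeoutError) as err:
            last_err = err
    raise last_err  # type: ignore[misc]


def fetch_seed_records(
    seed: str,
    providers: list[ProviderConfig],
    mode: str = "offline",
    offline_root: str | Path | None = None,
    timeout: float = 30.0,
) -> tuple[list[RawRecord], list[ProviderStatus], list[MalformedLine]]:
    """Collect MITAB records for one validated seed from every provider.

    Returns the concatenated records (each tagged with its source
    database), one status per configured provider, and any malformed
    lines encountered while parsing.  Raises
    :class:`NoDataSourceError` only when *no* provider responded.
    """
    if mode not in ("live", "offline"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "offline" and offline_root is None:
        raise ValueError("offline mode requires offline_root")

    records: list[RawRecord] = []
    statuses: list[ProviderStatus] = []
    malformed: list[MalformedLine] = []
    for provider in providers:
        if not provider.enabled:
            statuses.append(ProviderStatus(provider.name, "skipped"))
            continue
        try:
            if mode == "offline":
                path = Path(offline_root) / provider.name / f"{seed}.mitab"
                result = parse_mitab_file(path, provider.name)
            else:
                text = _fetch_live(provider, seed, timeout)
                result = parse_mitab(text, provider.name)
        except OSError:
            statuses.append(ProviderStatus(provider.name, "failed"))
            continue
        records.extend(result.records)
        malformed.extend(result.malformed)
        statuses.append(
            ProviderStatus(provider.name, "responded", len(result.records))
        )
    if not any(s.state == "responded" for s in statuses):
        raise NoDataSourceError("no data source available")
    return records, statuses, malformed
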