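"""Optional retrieval of reference sequences from GenBank.

Fetched records are cached as FASTA under a local cache directory so a
record is downloaded at most once.  Offline use raises a clear
:class:`~exodel.errors.AccessionFetchError` instead of silently
substituting synthetic data.
"""

from __future__ import annotations

import re
from pathlib import Path

from .errors import AccessionFetchError
from .repeats import AnnotatedSequence
from .seqio import read_fasta, write_fasta

__all__ = ["fetch_accession", "default_cache_dir"]

_ACCESSION_RE = re.compile(r"^[A-Z]{1,4}_?\d{5,10}(\.\d+)?$")


def default_cache_dir() -> Path:
    return Path.home() / ".cache" / "exodel" / "accessions"


def fetch_accession(accession: str,
                    cache_dir: str | Path | None = None,
                    timeout_s: float = 30.0) -> AnnotatedSequence:
    """Fetch a nucleotide record by accession (sequence only, no annotation).

    Checks the cache first; otherwise downloads via NCBI E-utilities.
    Raises :class:`AccessionFetchError` for a malformed identifier, a
    network failure (offline environments), or a malformed record.
    """
    accession = (accession or "").strip()
    if not _ACCESSION_RE.match(accession):
        raise AccessionFetchError(f"malformed accession identifier: {accession!r}")
    cache = Path(cache_dir) if cache_dir is not None else default_cache_dir()
    cached = cache / f"{accession}.fasta"
    if cached.exists():
        record = read_fasta(cached)
        record.source = accession
        return record

    from urllib.error import URLError
    from urllib.request import urlopen

    url = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
           f"?db=nuccore&id={accession}&rettype=fasta&retmode=text")
    try:
        with urlopen(url, timeout=timeout_s) as resp:
            text = resp.read().decode()
    except (URLError, OSError, TimeoutError) as exc:
        raise AccessionFetchError(
            f"could not fetch {accession} from NCBI (offline?): {exc}") from exc
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise AccessionFetchError(f"malformed record returned for {accession}")
    seq = "".join(lines[1:]).upper()
    if not seq or set(seq) - set("ACGTN"):
        raise AccessionFetchError(f"non-nucleotide record returned for {accession}")
    cache.mkdir(parents=True, exist_ok=True)
    write_fasta(cached, {accession: seq})
    return AnnotatedSequence(seq, source=accession)
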