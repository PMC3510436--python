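"""Optional GenBank accession fetch (network access; never implicit).

Used only by the ``trnapanel fetch-panel`` command. All core code paths
accept local FASTA instead.
"""

from __future__ import annotations

import urllib.parse
import urllib.request
from pathlib import Path

from .io_formats import PanelConfig

EFETCH_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch_accession_fasta(accession: str, timeout: float = 30.0) -> str:
    """Download one nucleotide accession as FASTA text."""
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH_URL}?{query}", timeout=timeout) as resp:
        text = resp.read().decode()
    if not text.startswith(">"):
        raise RuntimeError(f"unexpected efetch response for {accession!r}")
    return text


def fetch_panel_genomes(config: PanelConfig, out_dir: Path,
                        timeout: float = 30.0) -> list[Path]:
    """Download every panel species' reference genome to ``out_dir``.

    File names are the species with spaces replaced by underscores.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for entry in config.entries:
        text = fetch_accession_fasta(entry.accession, timeout=timeout)
        path = out_dir / (entry.species.replace(" ", "_") + ".fasta")
        path.write_text(text)
        written.append(path)
    return written
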