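#!/usr/bin/env python
"""Fetch the 11 β-globin benchmark regions from GenBank (network required).

Downloads each accession via NCBI efetch, extracts the 1-based inclusive
sub-region recorded in ``fpe.reference.BETA_GLOBIN_REGIONS``, and writes
one cleaned FASTA file per species into tests/data/beta_globin/, where
the full-data integration tests look for them:

    python scripts/fetch_beta_globin.py [--out-dir tests/data/beta_globin]
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

from fpe.io_prep import RawSequenceRecord, preprocess
from fpe.reference import BETA_GLOBIN_REGIONS
from fpe.testdata import write_fixture_fasta

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch_fasta(accession: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        return resp.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--out-dir", type=Path,
        default=Path(__file__).resolve().parent.parent / "tests" / "data" / "beta_globin",
    )
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for species, (accession, start, end) in BETA_GLOBIN_REGIONS.items():
        text = fetch_fasta(accession)
        body = "".join(text.splitlines()[1:])
        # slice on raw GenBank coordinates first, then clean, so that any
        # ambiguity characters in the record cannot shift the region
        raw_region = body[start - 1 : end]
        region = preprocess(
            RawSequenceRecord(id=species, description=accession, residues=raw_region)
        )
        write_fixture_fasta(args.out_dir / f"{species}.fa", [region])
        print(f"{species}: {accession} {start}-{end} -> {region.length} nt")
        time.sleep(0.4)  # stay under NCBI's unauthenticated rate limit


if __name__ == "__main__":
    main()
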