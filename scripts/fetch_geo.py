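#!/usr/bin/env python
"""Download GEO series-matrix files for the external validation cohorts.

Convenience only — nothing in the package or its tests requires these
downloads. Files land uncompressed under the given output directory and can
be read with ``read_expression_table(path, format="series_matrix")``.

Usage:
    python scripts/fetch_geo.py --out scratch/geo [GSE41258 GSE10961 GSE41568]
"""

from __future__ import annotations

import argparse
import gzip
import shutil
import urllib.request
from pathlib import Path

DEFAULT_ACCESSIONS = ("GSE41258", "GSE10961", "GSE41568")
URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/{stub}nnn/{acc}/matrix/"
    "{acc}_series_matrix.txt.gz"
)


def fetch(accession: str, out_dir: Path) -> Path:
    stub = accession[:-3]
    url = URL.format(stub=stub, acc=accession)
    gz_path = out_dir / f"{accession}_series_matrix.txt.gz"
    txt_path = gz_path.with_suffix("")
    print(f"downloading {url}")
    urllib.request.urlretrieve(url, gz_path)
    with gzip.open(gz_path, "rb") as src, open(txt_path, "wb") as dst:
        shutil.copyfileobj(src, dst)
    gz_path.unlink()
    print(f"wrote {txt_path}")
    return txt_path


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("accessions", nargs="*", default=list(DEFAULT_ACCESSIONS))
    parser.add_argument("--out", type=Path, default=Path("scratch/geo"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in args.accessions or DEFAULT_ACCESSIONS:
        fetch(acc, args.out)


if __name__ == "__main__":
    main()
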