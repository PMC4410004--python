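"""Convert a COSMIC mutant-export TSV to the reference-mutation dialect.

Maps the COSMIC columns onto the four-column table consumed by
``somdriver build-ref``:

    gene <TAB> sample <TAB> cds_pos <TAB> variant_class

COSMIC "Mutation Description" strings are translated to the standard MAF
``Variant_Classification`` vocabulary; descriptions without a MAF
equivalent pass through unchanged and are EXCLUDED downstream.  The CDS
position is parsed from the HGVS-style "Mutation CDS" field.

Usage:
    python scripts/convert_cosmic.py COSMIC_export.tsv reference.tsv
"""

from __future__ import annotations

import argparse
import csv
import sys

from somdriver.io import atomic_write

# COSMIC mutant-export column names (tab-separated export).
GENE_COLUMN = "Gene name"
SAMPLE_COLUMN = "ID_sample"
CDS_COLUMN = "Mutation CDS"
DESCRIPTION_COLUMN = "Mutation Description"

# COSMIC "Mutation Description" -> MAF Variant_Classification
DESCRIPTION_MAP = {
    "substitution - missense": "Missense_Mutation",
    "substitution - nonsense": "Nonsense_Mutation",
    "substitution - coding silent": "Silent",
    "deletion - frameshift": "Frame_Shift_Del",
    "insertion - frameshift": "Frame_Shift_Ins",
    "deletion - in frame": "In_Frame_Del",
    "insertion - in frame": "In_Frame_Ins",
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("cosmic_tsv")
    parser.add_argument("out_tsv")
    args = parser.parse_args()

    with open(args.cosmic_tsv, newline="") as infile, atomic_write(args.out_tsv) as out:
        reader = csv.DictReader(infile, delimiter="\t")
        missing = {GENE_COLUMN, SAMPLE_COLUMN, CDS_COLUMN, DESCRIPTION_COLUMN} - set(
            reader.fieldnames or []
        )
        if missing:
            sys.exit(f"missing COSMIC columns: {', '.join(sorted(missing))}")
        out.write("gene\tsample\tcds_pos\tvariant_class\n")
        n = 0
        for row in reader:
            gene = row[GENE_COLUMN].split("_")[0]  # strip transcript suffix
            description = row[DESCRIPTION_COLUMN].strip().lower()
            variant_class = DESCRIPTION_MAP.get(description, row[DESCRIPTION_COLUMN])
            out.write(f"{gene}\t{row[SAMPLE_COLUMN]}\t{row[CDS_COLUMN]}\t{variant_class}\n")
            n += 1
    print(f"wrote {n} rows to {args.out_tsv}", file=sys.stderr)


if __name__ == "__main__":
    main()
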