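#!/usr/bin/env python
"""Optional validation: profile naturally occurring CRISPR spacers and
separators from user-supplied FASTA files.

The collections of natural Cas12a spacers and separator sequences are
distributed as supplementary material of the primary literature and are
not bundled here.  Given those files, this script recomputes the summary
statistics the design rules rest on: spacer count, mean/range GC, the
3'-anchored GC profile, and (for an externally aligned separator set)
the separator count, per-column GC and the IUPAC consensus whose 5' end
reads GTYTA.

Usage:
    python scripts/profile_natural_sequences.py --spacers spacers.fasta
    python scripts/profile_natural_sequences.py --separators sep_aln.fasta
"""

from __future__ import annotations

import argparse

from casarray.seqcore import read_fasta
from casarray.seqstats import (
    anchor_3prime,
    column_gc_profile,
    iupac_consensus,
    read_aligned_fasta,
    spacer_set_summary,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--spacers", help="FASTA of natural spacers (25-36 nt)")
    parser.add_argument("--separators", help="gapped FASTA of aligned separators")
    parser.add_argument("--target-length", type=int, default=25,
                        help="3'-anchored stack length for spacers")
    args = parser.parse_args()
    if not args.spacers and not args.separators:
        parser.error("provide --spacers and/or --separators")

    if args.spacers:
        entries = read_fasta(args.spacers)
        seqs = [s for _, s in entries]
        summary = spacer_set_summary(seqs)
        print(f"spacers: n = {summary['count']}")
        print(f"mean GC = {100 * summary['mean_gc']:.0f}%")
        print(f"range   = {100 * summary['min_gc']:.0f}-{100 * summary['max_gc']:.0f}%")
        aln = anchor_3prime(seqs, target_length=args.target_length)
        prof = column_gc_profile(aln)
        print("3'-anchored GC profile (start, width, gc):")
        for start, width, gc in prof.windows:
            print(f"  {start:3d} {width} {gc:.3f}")

    if args.separators:
        aln = read_aligned_fasta(args.separators)
        print(f"separators: n = {len(aln)}")
        print(f"consensus = {iupac_consensus(aln)}")
        prof = column_gc_profile(aln)
        mean_gc = sum(w[2] for w in prof.windows if w[2] == w[2]) / len(prof.windows)
        print(f"mean windowed GC = {100 * mean_gc:.0f}%")


if __name__ == "__main__":
    main()
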