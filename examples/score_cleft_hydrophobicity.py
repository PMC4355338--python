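"""Total active-site cleft hydrophobicity for the carbonic anhydrase family.

Loads the bundled cleft residue table (nine positions in CA II numbering,
eleven isoforms), sums Kyte-Doolittle hydropathy values down each column,
and compares the rounded totals with the published ones. Higher totals
mean a more hydrophobic cleft: CA II (26) and CA IX (23) stand out, which
is why hydrophobic-tailed inhibitors favor them.
"""

import isopocket as ip

table = ip.read_residue_table(ip.bundled_fixture("table4_cleft"))
printed = ip.bundled_printed_totals()

print(f"{'isoform':>8} {'residues':>12} {'raw':>6} {'rounded':>8} {'published':>10}")
for score in ip.score_family(table):
    residues = "".join(r for _, r, _ in score.contributions)
    ref = printed[score.isoform]
    flag = "" if ref == score.rounded else "  <- recomputation disagrees"
    print(f"{score.isoform:>8} {residues:>12} {score.raw:>6.1f} "
          f"{score.rounded:>8d} {ref:>10d}{flag}")
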