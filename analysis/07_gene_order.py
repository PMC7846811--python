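"""Compare the rearranged gene order against the standard vertebrate one.

Reports moved genes, duplicated elements (including the pseudogenized
second tRNA-Lys), extra non-coding blocks, and the breakpoint count on the
shared single-copy gene set.
"""

from common import parse_args, write_json

from mitotwin.gene_order import STANDARD_VERTEBRATE, TUATARA, compare_orders


def main() -> None:
    parse_args(__doc__)
    rep = compare_orders(TUATARA, STANDARD_VERTEBRATE)
    payload = {
        "moved_genes": rep.moved_genes,
        "duplicated_elements": rep.duplicated_elements,
        "extra_noncoding_blocks": rep.extra_noncoding_blocks,
        "breakpoint_count": rep.breakpoint_count,
    }
    path = write_json("07_gene_order.json", payload)
    print(f"{rep.breakpoint_count} breakpoints vs the standard vertebrate "
          f"order; moved genes: {', '.join(rep.moved_genes)}.")
    print(f"Duplicated elements: {', '.join(rep.duplicated_elements)}; "
          f"{rep.extra_noncoding_blocks} extra non-coding block(s).")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
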