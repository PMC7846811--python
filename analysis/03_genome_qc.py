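"""Validate that both simulated molecules look mitochondrial.

Checks the heavy-strand guanine deficit, clean translation of all 13
protein-coding genes under the vertebrate mitochondrial code, cloverleaf
folds for all 22 tRNAs, and stem-loop candidates in the tRNA-Asn/tRNA-Cys
region that could serve as a light-strand replication origin.
"""

from common import parse_args, write_json

from mitotwin.qc import base_composition, fold_trna, scan_ol_stemloop, translate_cds
from mitotwin.simulate import SimConfig, simulate_truth_set


def main() -> None:
    args = parse_args(__doc__)
    truth = simulate_truth_set(SimConfig(seed=args.seed))
    payload = {}
    for name, g in (("M1", truth.genome_m1), ("M2", truth.genome_m2)):
        comp = base_composition(g)
        trans = translate_cds(g)
        trnas = [a for a in g.annotations if a.kind == "tRNA"]
        folds = {a.name: fold_trna(g.feature_sequence(a)) for a in trnas}
        hairpins = scan_ol_stemloop(g)
        payload[name] = {
            "guanine_pct_heavy": round(comp.guanine_pct_heavy, 1),
            "translation_pass": trans.passed,
            "incomplete_stops": [c.gene for c in trans.per_cds
                                 if not c.stop_complete],
            "trnas_folded": sum(s.folded for s in folds.values()),
            "n_trnas": len(folds),
            "d_arm_replacement_loops": [n for n, s in folds.items()
                                        if s.d_arm_replacement_loop],
            "ol_candidates": len(hairpins),
        }
        print(f"{name}: G {payload[name]['guanine_pct_heavy']}% on heavy "
              f"strand; 13 CDS translate cleanly: {trans.passed}; "
              f"{payload[name]['trnas_folded']}/22 tRNAs fold; "
              f"{len(hairpins)} O_L-like stem-loop candidate(s).")
    path = write_json("03_qc.json", payload)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
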