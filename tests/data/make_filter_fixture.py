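"""Generate the 50-record toy VCF and its filter answer key.

This script is deliberately independent of the package: it writes the VCF
text directly and applies the site-filter and clustered-SNP rules with its
own literal implementation, so the key can serve as a fixed external answer
sheet for the filter stages.  Run from the repository root:

    python tests/data/make_filter_fixture.py
"""

import json
import random
from pathlib import Path

HERE = Path(__file__).parent

RULES_FINAL = {"QD": ("lt", 2.0), "FS": ("gt", 30.0)}
RULES_STRICT = {
    "QD": ("lt", 2.0),
    "FS": ("gt", 60.0),
    "MQ": ("lt", 40.0),
    "MQRankSum": ("lt", -12.5),
    "ReadPosRankSum": ("lt", -8.0),
}


def fails(info, rules):
    for key, (op, thr) in rules.items():
        if key not in info:
            continue
        v = info[key]
        if (op == "lt" and v < thr) or (op == "gt" and v > thr):
            return True
    return False


def cluster_removed(positions, window=35, count=3):
    """Positions belonging to any run of >= count SNPs spanning <= window."""
    pos = sorted(positions)
    out = set()
    for i in range(len(pos) - count + 1):
        if pos[i + count - 1] - pos[i] <= window:
            out.update(pos[i : i + count])
    return out


def main():
    rnd = random.Random(20240917)
    records = []
    pos = 100
    for i in range(50):
        # mix of spacings so some runs trip the 35-bp/3-SNP cluster rule
        pos += rnd.choice([8, 10, 12, 15, 40, 200])
        info = {}
        info["QD"] = round(rnd.choice([0.5, 1.9, 2.0, 2.1, 8.0, 25.0, 30.0, 18.0]), 2)
        info["FS"] = round(rnd.choice([0.0, 2.0, 5.0, 29.9, 30.0, 30.1, 45.0, 61.0, 1.0, 3.0]), 2)
        if rnd.random() < 0.8:
            info["MQ"] = round(rnd.choice([35.0, 40.0, 55.0, 60.0]), 2)
        if rnd.random() < 0.7:
            info["MQRankSum"] = round(rnd.uniform(-14, 2), 2)
        if rnd.random() < 0.7:
            info["ReadPosRankSum"] = round(rnd.uniform(-9, 2), 2)
        if rnd.random() < 0.1:
            info = {}  # fully unannotated site: must pass everything
        records.append(("Scaffold_1", pos, info))

    lines = [
        "##fileformat=VCFv4.2",
        *(
            f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">'
            for k in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")
        ),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "##contig=<ID=Scaffold_1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2",
    ]
    for scaffold, p, info in records:
        info_s = ";".join(f"{k}={v:g}" for k, v in info.items()) or "."
        lines.append(
            f"{scaffold}\t{p}\t.\tA\tG\t.\tPASS\t{info_s}\tGT:AD\t0/1:10,12\t0/0:20,0"
        )
    (HERE / "filter_fixture.vcf").write_text("\n".join(lines) + "\n")

    final_kept = [p for _, p, info in records if not fails(info, RULES_FINAL)]
    strict_kept = [p for _, p, info in records if not fails(info, RULES_STRICT)]
    clustered = cluster_removed(final_kept)
    final_then_cluster = [p for p in final_kept if p not in clustered]
    key = {
        "n_records": len(records),
        "final_kept": final_kept,
        "strict_kept": strict_kept,
        "final_then_cluster_kept": final_then_cluster,
    }
    (HERE / "filter_fixture_key.json").write_text(json.dumps(key, indent=1))
    print(
        f"wrote {len(records)} records; final keeps {len(final_kept)}, "
        f"strict keeps {len(strict_kept)}, cluster filter keeps {len(final_then_cluster)}"
    )


if __name__ == "__main__":
    main()
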