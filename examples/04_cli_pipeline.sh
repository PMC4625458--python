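#!/usr/bin/env bash
# Full shell pipeline: simulate -> index -> predict -> evaluate.
# Writes everything under ./scratch/cli-demo and prints the summary row
# of the evaluation report (per-query metrics plus dataset means).
set -euo pipefail

out=scratch/cli-demo
rm -rf "$out"
mkdir -p "$out"

gota simulate --seed 7 --n-pubs 200 --n-terms 40 --n-queries 20 \
    --out "$out/fixture"

gota index \
    --obo "$out/fixture/ontology.obo" \
    --corpus "$out/fixture/corpus.jsonl" \
    --annotations "$out/fixture/annotations.tsv" \
    --out "$out/index"

gota predict --index "$out/index" \
    --query "$out/fixture/queries.jsonl" --top 10 \
    > "$out/predictions.tsv"

gota evaluate --index "$out/index" \
    --gold "$out/fixture/query_annotations.tsv" \
    --predictions "$out/predictions.tsv" \
    --report "$out/report.tsv"
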