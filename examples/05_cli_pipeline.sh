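#!/usr/bin/env bash
# End-to-end shell pipeline: simulate -> similarity -> fit -> cv.
# All outputs are plain TSV/JSON under ./scratch_example/.
set -euo pipefail

out=scratch_example
rm -rf "$out" && mkdir -p "$out"

dimr simulate --scenario separable3 --seed 11 --out "$out/data"

dimr similarity \
    --attributes-file "$out/data/attributes.tsv" \
    --schema "$out/data/schema.yaml" \
    --measure dimrs --out "$out/S.tsv"

dimr fit --data "$out/data/data.tsv" --similarity "$out/S.tsv" \
    --iters 400 --burn-in 200 --seed 11 --out "$out/fit"

dimr cv --data "$out/data/data.tsv" --similarity "$out/S.tsv" \
    --folds 5 --seed 11 --out "$out/cv.tsv"

echo "--- estimated partition sizes ---"
cut -f2 "$out/fit/partition.tsv" | tail -n +2 | sort | uniq -c
echo "--- cross-validated error ---"
column -t "$out/cv.tsv"
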