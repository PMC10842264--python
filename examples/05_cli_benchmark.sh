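#!/bin/sh
# End-to-end shell workflow: write a benchmark case to disk, screen the
# library directory against the target map, and validate the control.
set -e
OUT=$(mktemp -d)

voxmatch bench --seed 7 --decoys 10 --snr 1.5 --out "$OUT/case"

TRUTH=$(python -c "import json;print(json.load(open('$OUT/case/manifest.json'))['truth_id'])")
CUTOFF=$(python -c "import json;print(json.load(open('$OUT/case/manifest.json'))['params']['cutoff'])")

voxmatch scan --target "$OUT/case/target.mrc" --library "$OUT/case/library" \
    --res 6.0 --cutoff "$CUTOFF" --deg 15.0 --top 5 --out "$OUT/hits.tsv"
cat "$OUT/hits.tsv"

voxmatch control --target "$OUT/case/target.mrc" \
    --library "$OUT/case/library" --expected "$TRUTH" \
    --cutoff "$CUTOFF" --k 1 \
    && echo "control validated: $TRUTH is the top hit"

rm -rf "$OUT"
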