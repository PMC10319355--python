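#!/usr/bin/env bash
# Batch pipeline from the shell: simulate a small cohort, measure it,
# and inspect the per-image table and per-condition boxplot summary.
set -euo pipefail

wormquant simulate --out-dir scratch/demo/images --n-worms 5 --seed 11 \
    --pixels-per-um 2.0 --length-range 700,900
wormquant measure --input-dir scratch/demo/images --out-dir scratch/demo/measurements

echo "--- per-image measurements ---"
column -s, -t < scratch/demo/measurements/measurements.csv
echo "--- group summary (25/50/75 percentiles, min-max whiskers) ---"
column -s, -t < scratch/demo/measurements/summary.csv

# manual lumen mode: average externally measured width pairs
wormquant lumen --manual-widths 4.2,5.6 --out scratch/demo/lumen.csv
cat scratch/demo/lumen.csv
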