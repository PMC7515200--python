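#!/bin/sh
# Full pipeline through the CLI: simulate inputs, then run every stage.
# Each stage writes its artifacts plus a manifest with input hashes,
# parameters and the seed; re-running with the same seed is byte-identical.
set -e

WORK="${1:-/tmp/enhancerlink_demo}"

enhancerlink simulate --seed 1 --outdir "$WORK/inputs"
enhancerlink all --config "$WORK/inputs/run_config.yaml" --outdir "$WORK/run"

echo "---"
head -5 "$WORK/run/tr_ranks.tsv"
echo "---"
cat "$WORK/run/motif_fraction.tsv"
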