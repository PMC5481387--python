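#!/bin/sh
# End-to-end command-line workflow: simulate benchmark ROIs, analyse the
# localization tables, and score the recovered clusters against the truth.
#
# Run from the repository root:  sh examples/05_cli_workflow.sh
set -e

WORK=$(mktemp -d)

# 1. Simulate two Standard Condition ROIs (localizations + ground truth).
bayescluster3d simulate --condition standard --n-roi 2 --seed 1 --out "$WORK/sim"

# 2. Analyse the localization tables.  A coarser sweep grid than the
#    default keeps this demo fast; drop the grid flags for real analyses.
bayescluster3d analyze "$WORK"/sim/*_localizations.csv \
    --out "$WORK/results" \
    --rmin 40 --rmax 160 --rstep 40 --tmin 0 --tmax 150 --tstep 75

# 3. Compare detected clusters with the simulated truth.
bayescluster3d evaluate --truth-dir "$WORK/sim" \
    --results-dir "$WORK/results" --out "$WORK/recovery.csv"

echo
echo "condition summary:"
cat "$WORK/results/condition_summary.csv"
echo
echo "recovery vs truth:"
cat "$WORK/recovery.csv"

rm -rf "$WORK"
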