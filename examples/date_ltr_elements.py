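"""Date LTR retrotransposon insertions from LTR-pair identity.

The paired LTRs of an element are identical at insertion; divergence K
accumulates at 2r per year, so the age is T = K/(2r). Uses a small
in-memory pass list; point `date_pass_list` at a real LTR-RETRIEVER
`*.pass.list` file in the same way.
"""

import pandas as pd

import kmerpatch as kp

pass_list = pd.DataFrame({
    "LTR_loc": ["chr1:10000..18500", "chr1:52000..61000", "chr2:700..9400"],
    "Identity": [1.0, 0.9956, 0.9780],
})

result = kp.date_pass_list(pass_list, r=2.2e-9, bin_my=1.0)
print(result.to_frame().to_string(index=False))
print("\nage histogram (My bins):")
print(result.histogram.to_string(index=False))
# identity 0.9956 gives K=0.0044 and exactly 1.0 My at r=2.2e-9; an
# identical pair (identity 1.0) dates to 0 — a very recent insertion.
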