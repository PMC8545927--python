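# miRNA spelling fixes applied after case-folding and "hsa-" stripping.
# Format: wrong<TAB>right. Lines starting with # are ignored.
# "leg-7g" is a known misspelling of the let-7g family.
leg-7g-3p	let-7g-3p
leg-7g-5p	let-7g-5p
leg-7g	let-7g
# Candidate fix, NOT applied by default: "mir-34a-4p" (no -4p arm exists)
# may be a misprint of mir-34a-5p, but the source spelling is preserved.
# mir-34a-4p	mir-34a-5p
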