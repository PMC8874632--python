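# Published pKa predictions for the Veraguamides A-G. NOTE: these values
# are not reproducible from the stated hardness QSAR (16.3088 - 0.8268*eta)
# with the published hardness values, which give ~11.2-11.6 with the
# opposite hardness ordering; the source of the published numbers is
# undocumented. Shipped for reference only; no computation targets them.
molecule_id,pka
Veraguamide A,12.36
Veraguamide B,12.40
Veraguamide C,12.55
Veraguamide D,12.58
Veraguamide E,12.60
Veraguamide F,12.50
Veraguamide G,12.62
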