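# Limb-development gene symbols used to annotate divergent-expression sets.
# One symbol per line; edit or replace via --annotation.
Col2a1
Ctnnb1
Evx2
Fbn2
Fgf8
Grem1
Hand1
Hoxa13
Hoxd9
Hoxd11
Hoxd12
Hoxd13
Isl1
Lnp
Mecom
Med1
Msx1
Myog
Pax1
Pitx1
Prrx1
Prrx2
Rarb
Shh
Tbx4
Tbx5
Tnnt2
Twist1
Wnt5a
Zbtb16
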