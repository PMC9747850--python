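# Material library: source hardware and phantom media.
# format: name ; density g/cm3 ; El:mass-percent El:mass-percent ...
# Notes on the bundled compositions:
#  * titanium: the alloy is Ti-6Al-4V; the published composition row lists
#    Al 6, Ti 9, V 4 (sum 19%), an evident misprint of the titanium
#    balance.  The bundled row sets Ti to 90%.  strict_titanium (below,
#    disabled by default) keeps the printed row, renormalized, for
#    sensitivity checks.
#  * bone: implemented exactly as published (K 20.993% and no matching
#    Ca entry, which looks like a K/Ca transposition in the source
#    document); kept as printed rather than silently corrected.
#  * cartilage (printed sum 99.7%) and stainless steel (printed sum
#    99.0%) do not close to 100; fractions are renormalized at load.
#  * the trace element printed as "Z" in tissue rows is zinc.
titanium ; 4.42 ; Al:6 Ti:90 V:4
lung ; 0.26 ; H:10.1278 C:10.231 N:2.865 O:75.7072 Na:0.184 Mg:0.073 P:0.08 Si:0.225 Cl:0.266 K:0.194 Ca:0.009 Fe:0.037 Zn:0.001
muscle ; 1.05 ; H:10.0637 C:10.783 N:2.768 O:75.4773 Na:0.075 Mg:0.019 P:0.18 Si:0.241 Cl:0.079 K:0.302 Ca:0.003 Fe:0.004 Zn:0.005
bone ; 1.92 ; H:4.7234 C:14.433 N:4.199 O:44.6096 Mg:0.22 P:10.497 Si:0.315 K:20.993 Zn:0.01
adipose ; 0.92 ; H:11.9477 C:63.724 N:0.797 O:23.2333 Na:0.05 Mg:0.002 P:0.016 Si:0.073 Cl:0.119 K:0.032 Ca:0.002 Fe:0.002 Zn:0.002
cartilage ; 1.1 ; H:9.6 C:9.6 N:2.2 O:74.4 Na:0.5 P:2.2 Si:0.9 Cl:0.3
stainless steel ; 8 ; C:0.08 P:0.045 Cr:19 Mn:2 Fe:68.375 Ni:9.5
peek ; 1.31 ; H:4.1954 C:79.1557 O:16.6489
pmma ; 1.19 ; H:8.0542 C:59.984 O:31.9618
water ; 1 ; H:11.1894 O:88.8106
air ; 0.0012 ; H:0.0732 C:0.0123 N:75.0325 O:23.6077 Ar:1.2743
vacuum ; 0.000001 ; H:100
iridium seed ; 22.42 ; Ir:100
304 ; 5.6 ; C:0.08 N:0.1 Si:0.75 P:0.045 S:0.03 Cr:19 Mn:2 Fe:68.745 Ni:9.25
316L ; 8.03 ; C:0.03 N:0.1 Si:0.75 P:0.045 S:0.03 Cr:17 Mn:2 Fe:65.545 Ni:12 Mo:2.5
#strict_titanium ; 4.42 ; Al:6 Ti:9 V:4
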