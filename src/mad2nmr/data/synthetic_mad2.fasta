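>synthetic_mad2_standin length=205 note=SYNTHETIC stand-in, not the real Mad2 sequence; reproduces the coordinate landmarks used by the construct definitions (TAKDDSAPR at 109-117, Trp reporters at 75/167, Arg133, Leu13) and a 6-proline composition
MCTGLSACLNELLYSGTQYVHRWFHQLDWPQWYNVIMSMQNTGLVFFFRKDVFIVALDEP
CNKRIFVLCQVDYFWVTHLDKDDCTGYFNPFMCKMNFRSYLTWKVCEMTAKDDSAPRCYE
VFCIAEQHGRSIRHGFDWSATRQQGKDWWPAICYRSDDVMGQCAKQWHWNMTQRWFLGVK
IRICQMRFVPWGCMNDIVLEHLSAD
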