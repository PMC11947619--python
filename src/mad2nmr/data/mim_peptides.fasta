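>Cdc20_MIM_111-138
EHQKAWALNLNGFDVEEAKILRLSGKPQ
>Cdc20_MIM_123-137
FDVEEAKILRLSGKP
>Cdc20_MIM_123-152
FDVEEAKILRLSGKPQNAPEGYQNRLKVLY
>Cdc20_MIM_138-152
QNAPEGYQNRLKVLY
>Mad1_MIM_529-550
RALQGDYDQSRTKVLHMSLNPT
>MBP1_MIM
SWYSYPPPQRAV
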