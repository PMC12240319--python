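raw_name,generic,atc_code
ATORVASTATIN,atorvastatin,C10AA05
ATORVASTATIN CALCIUM,atorvastatin,C10AA05
ATORVASTATIN CALCIUM TRIHYDRATE,atorvastatin,C10AA05
LIPITOR,atorvastatin,C10AA05
SORTIS,atorvastatin,C10AA05
TAHOR,atorvastatin,C10AA05
TORVAST,atorvastatin,C10AA05
CERIVASTATIN,cerivastatin,C10AA06
CERIVASTATIN SODIUM,cerivastatin,C10AA06
BAYCOL,cerivastatin,C10AA06
LIPOBAY,cerivastatin,C10AA06
FLUVASTATIN,fluvastatin,C10AA04
FLUVASTATIN SODIUM,fluvastatin,C10AA04
LESCOL,fluvastatin,C10AA04
LESCOL XL,fluvastatin,C10AA04
LOCHOL,fluvastatin,C10AA04
LOVASTATIN,lovastatin,C10AA02
MEVACOR,lovastatin,C10AA02
ALTOPREV,lovastatin,C10AA02
ALTOCOR,lovastatin,C10AA02
PITAVASTATIN,pitavastatin,C10AA08
PITAVASTATIN CALCIUM,pitavastatin,C10AA08
PITAVASTATIN MAGNESIUM,pitavastatin,C10AA08
LIVALO,pitavastatin,C10AA08
LIVAZO,pitavastatin,C10AA08
ZYPITAMAG,pitavastatin,C10AA08
PRAVASTATIN,pravastatin,C10AA03
PRAVASTATIN SODIUM,pravastatin,C10AA03
PRAVACHOL,pravastatin,C10AA03
SELEKTINE,pravastatin,C10AA03
LIPOSTAT,pravastatin,C10AA03
MEVALOTIN,pravastatin,C10AA03
ROSUVASTATIN,rosuvastatin,C10AA07
ROSUVASTATIN CALCIUM,rosuvastatin,C10AA07
CRESTOR,rosuvastatin,C10AA07
EZALLOR,rosuvastatin,C10AA07
ROSUZET,rosuvastatin,C10AA07
SIMVASTATIN,simvastatin,C10AA01
ZOCOR,simvastatin,C10AA01
SIMVACOR,simvastatin,C10AA01
FLOLIPID,simvastatin,C10AA01
LIPEX,simvastatin,C10AA01
SIMLUP,simvastatin,C10AA01
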