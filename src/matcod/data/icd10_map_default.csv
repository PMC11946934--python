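# version=2026.1-reconstructed
code_prefix,group,subgroup
O00,abortion,
O01,abortion,
O02,abortion,
O03,abortion,
O04,abortion,
O05,abortion,
O06,abortion,
O07,abortion,
O08,abortion,
O09,other_direct,other
O10,indirect,
O11,hypertension,
O12,hypertension,
O13,hypertension,
O14,hypertension,
O15,hypertension,
O16,hypertension,
O17,other_direct,other
O18,other_direct,other
O19,other_direct,other
O20,haemorrhage,antepartum
O21,other_direct,other
O22,other_direct,other
O23,sepsis,antepartum
O24,indirect,
O25,indirect,
O26,other_direct,other
O27,other_direct,other
O28,other_direct,other
O29,other_direct,anaesthesia
O30,other_direct,other
O31,other_direct,other
O32,other_direct,other
O33,other_direct,other
O34,other_direct,other
O35,other_direct,other
O36,other_direct,other
O37,other_direct,other
O38,other_direct,other
O39,other_direct,other
O40,other_direct,other
O41,other_direct,other
O42,other_direct,other
O43,other_direct,other
O44,haemorrhage,antepartum
O45,haemorrhage,antepartum
O46,haemorrhage,antepartum
O47,other_direct,other
O48,other_direct,other
O49,other_direct,other
O50,other_direct,other
O51,other_direct,other
O52,other_direct,other
O53,other_direct,other
O54,other_direct,other
O55,other_direct,other
O56,other_direct,other
O57,other_direct,other
O58,other_direct,other
O59,other_direct,other
O60,other_direct,other
O61,other_direct,other
O62,other_direct,other
O63,other_direct,other
O64,other_direct,obstructed_labour
O65,other_direct,obstructed_labour
O66,other_direct,obstructed_labour
O67,haemorrhage,intrapartum
O68,other_direct,other
O69,other_direct,other
O70,other_direct,obstetric_trauma
O71,other_direct,obstetric_trauma
O72,haemorrhage,postpartum
O73,other_direct,other
O74,other_direct,anaesthesia
O75,other_direct,other
O753,sepsis,intrapartum
O76,other_direct,other
O77,other_direct,other
O78,other_direct,other
O79,other_direct,other
O80,other_direct,other
O81,other_direct,other
O82,other_direct,other
O83,other_direct,other
O84,other_direct,other
O85,sepsis,postpartum
O86,sepsis,postpartum
O87,other_direct,other
O88,embolism,
O89,other_direct,anaesthesia
O90,other_direct,other
O91,other_direct,other
O92,other_direct,other
O93,other_direct,other
O94,other_direct,other
O95,other_direct,other
O96,late,
O97,late,
X60,suicide,
X61,suicide,
X62,suicide,
X63,suicide,
X64,suicide,
X65,suicide,
X66,suicide,
X67,suicide,
X68,suicide,
X69,suicide,
X70,suicide,
X71,suicide,
X72,suicide,
X73,suicide,
X74,suicide,
X75,suicide,
X76,suicide,
X77,suicide,
X78,suicide,
X79,suicide,
X80,suicide,
X81,suicide,
X82,suicide,
X83,suicide,
X84,suicide,
O98,indirect,
O99,indirect,
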