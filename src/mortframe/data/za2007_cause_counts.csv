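region_id,cause,cause_count,total_deaths
Eastern Cape,Certain infectious and parasitic diseases (A00-B99),14505,42190
Eastern Cape,External (V01-Y98),5536,42190
Eastern Cape,Diseases of the respiratory system (J00-J99),5060,42190
Eastern Cape,Ill defined (R00-R99),4995,42190
Eastern Cape,Diseases of the circulatory system (I00-I99),3257,42190
Free State,Certain infectious and parasitic diseases (A00-B99),9982,31031
Free State,Diseases of the respiratory system (J00-J99),6001,31031
Free State,Ill defined (R00-R99),3307,31031
Free State,External (V01-Y98),2538,31031
Free State,Diseases of the circulatory system (I00-I99),2511,31031
Gauteng,Certain infectious and parasitic diseases (A00-B99),15149,56330
Gauteng,External (V01-Y98),8852,56330
Gauteng,Diseases of the respiratory system (J00-J99),7722,56330
Gauteng,Ill defined (R00-R99),7569,56330
Gauteng,Diseases of the circulatory system (I00-I99),5112,56330
KwaZulu-Natal,Certain infectious and parasitic diseases (A00-B99),32921,78323
KwaZulu-Natal,Ill defined (R00-R99),8709,78323
KwaZulu-Natal,External (V01-Y98),8697,78323
KwaZulu-Natal,Diseases of the respiratory system (J00-J99),8625,78323
KwaZulu-Natal,Diseases of the circulatory system (I00-I99),5519,78323
Limpopo,Certain infectious and parasitic diseases (A00-B99),7910,26947
Limpopo,Diseases of the respiratory system (J00-J99),4542,26947
Limpopo,Ill defined (R00-R99),4151,26947
Limpopo,External (V01-Y98),2613,26947
Limpopo,Diseases of the circulatory system (I00-I99),1980,26947
Mpumalanga,Certain infectious and parasitic diseases (A00-B99),10695,29918
Mpumalanga,Diseases of the respiratory system (J00-J99),5198,29918
Mpumalanga,External (V01-Y98),2877,29918
Mpumalanga,Diseases of the circulatory system (I00-I99),2332,29918
Mpumalanga,Diseases of the blood and immunity disorders (D50-D89),2103,29918
North West,Certain infectious and parasitic diseases (A00-B99),7835,25009
North West,Diseases of the respiratory system (J00-J99),4257,25009
North West,Ill defined (R00-R99),2873,25009
North West,External (V01-Y98),2741,25009
North West,Diseases of the circulatory system (I00-I99),2540,25009
Northern Cape,Certain infectious and parasitic diseases (A00-B99),2217,7760
Northern Cape,Diseases of the respiratory system (J00-J99),1126,7760
Northern Cape,External (V01-Y98),994,7760
Northern Cape,Ill defined (R00-R99),980,7760
Northern Cape,Diseases of the circulatory system (I00-I99),683,7760
Western Cape,Certain infectious and parasitic diseases (A00-B99),4722,17466
Western Cape,External (V01-Y98),4012,17466
Western Cape,Neoplasms (C00-D48),2128,17466
Western Cape,Diseases of the circulatory system (I00-I99),1977,17466
Western Cape,Diseases of the respiratory system (J00-J99),1190,17466
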