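source,detailed
1,store
grocery/supermarket,store
27,store
store - convenience type,store
28,store
store - no additional information,store
7,school
cafeteria in a k-12 school,school
2,full_service
restaurant with waiter/waitress,full_service
4,full_service
bar/tavern/lounge,full_service
5,full_service
restaurant - no additional information,full_service
3,quick_service
restaurant fast food/pizza,quick_service
6,quick_service
cafeteria not in a k-12 school,quick_service
14,quick_service
vending machine,quick_service
24,quick_service
sport/recreation/entertainment facility,quick_service
25,quick_service
street vendor/vending truck,quick_service
8,community_food_program
family/adult day care center,community_food_program
10,community_food_program
soup kitchen/shelter/food pantry,community_food_program
11,community_food_program
meals on wheels,community_food_program
12,community_food_program
community food program - other,community_food_program
13,community_food_program
community program - no additional information,community_food_program
19,homegrown
grown by you or someone you know,homegrown
20,homegrown
fish caught by you or someone you know,homegrown
9,other
child/adult home care,other
child care center,other
15,other
common coffee pot or snack tray,other
16,other
from someone else/gift,other
17,other
mail order purchase,other
18,other
residential dining facility,other
26,other
fundraiser sales,other
91,other
other,other
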